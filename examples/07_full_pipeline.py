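"""Run the whole config-driven pipeline end to end on synthetic data.

simulate -> deg -> overlap -> rank -> rwr -> ssgsea -> ora -> gsea, with a
manifest recording checksums and wall time per stage.
"""

from pathlib import Path

from netprior import PipelineConfig, run_pipeline

outdir = Path("scratch/example_run")
config = PipelineConfig(
    outdir=str(outdir),
    seed=1,
    synthetic={"n_genes": 1000},
    n_perm=199,
)
manifest = run_pipeline(config)

for stage in manifest.stages:
    print(f"{stage['stage']:10s} {stage['seconds']:7.2f}s  "
          f"{len(stage['outputs'])} output file(s)")
print(f"\nconsensus hubs: {(outdir / 'consensus_hubs.txt').read_text().split()}")
print(f"planted hub:    {(outdir / 'truth_hub.txt').read_text().split()}")
print(f"RWR top-3:      {[l.split()[1] for l in (outdir / 'rwr_ranking.tsv').read_text().splitlines()[1:4]]}")
# Interpretation: both prioritization routes nominate the planted hub; the
# manifest makes the run reproducible artifact by artifact.
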