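"""Config-driven end-to-end orchestration.

A :class:`PipelineConfig` (YAML-serializable) enables any subset of the
stages — simulate, deg, overlap, rank, rwr, ssgsea, ora, gsea — and
:func:`run_pipeline` executes the enabled stages in dependency order,
writing every stage's outputs plus a :class:`RunManifest` (config snapshot,
input/output SHA-256 checksums, wall time per stage). Pre-flight validation
checks that every enabled stage will find its inputs — either on disk or as
a product of an earlier enabled stage — before anything is computed, so a
misconfigured run never leaves partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._rng import substream
from .degscreen import DEGPartition, screen_degs
from .enrich import (
    compare_group_scores,
    gsea_permutation_p,
    ora,
    rank_by_log2fc,
    ssgsea_score,
)
from .graphio import (
    GeneSet,
    GeneSetCollection,
    read_de_table,
    read_edge_list,
    read_expression,
    read_gene_list,
    read_gmt,
    write_gene_list,
    write_ranked_scores,
)
from .netrank import RwrConfig, consensus, mc_rwr
from .overlap import overlap_report
from .synthetic import SyntheticSpec, gen_de_table, gen_expression, gen_ppi, gen_target_lists, gene_universe

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

_STAGE_ORDER = ("simulate", "deg", "overlap", "rank", "rwr", "ssgsea", "ora", "gsea")


@dataclass
class PipelineConfig:
    """All stage parameters and file paths for one pipeline run.

    Defaults encode the pipeline's canonical parameters: log2FC cutoff 0.5,
    significance 0.05, 10,000 walks of at most 100 steps with restart 0.1,
    consensus k = 3.
    """

    outdir: str = "netprior_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGE_ORDER))
    uppercase_symbols: bool = False

    # inputs (ignored for artifacts the simulate stage produces)
    edge_list: str | None = None
    de_table: str | None = None
    expression: str | None = None
    gmt: str | None = None
    target_lists: list[str] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)

    # simulate
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides
    n_target_sources: int = 4
    per_source_size: int = 20
    core_size: int = 5

    # deg
    lfc_cut: float = 0.5
    alpha: float = 0.05
    adjust: str = "bh"

    # rank
    k: int = 3
    epc_iters: int = 1000
    epc_keep: float = 0.5

    # rwr
    n_walks: int = 10_000
    max_steps: int = 100
    restart_prob: float = 0.1
    source_mode: str = "each_node"

    # enrichment
    ssgsea_alpha: float = 0.25
    gsea_exponent: float = 1.0
    n_perm: int = 999

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in _STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; expected {_STAGE_ORDER}")


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: list[dict] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _preflight(config: PipelineConfig) -> None:
    """Fail before any computation if an enabled stage will miss an input."""
    enabled = set(config.stages)
    simulated = "simulate" in enabled

    def available(path: str | None, produced_by_simulate: bool) -> bool:
        if produced_by_simulate and simulated:
            return True
        return path is not None and Path(path).exists()

    problems = []
    if "deg" in enabled and not available(config.de_table, True):
        problems.append("deg: no DE table and simulate disabled")
    if "overlap" in enabled:
        if "deg" not in enabled:
            problems.append("overlap: requires the deg stage")
        if not config.target_lists and not simulated:
            problems.append("overlap: no target lists and simulate disabled")
    if "rank" in enabled and not available(config.edge_list, True):
        problems.append("rank: no edge list and simulate disabled")
    if "rwr" in enabled and not available(config.edge_list, True):
        problems.append("rwr: no edge list and simulate disabled")
    if "ssgsea" in enabled:
        if not available(config.expression, True):
            problems.append("ssgsea: no expression matrix and simulate disabled")
        if not available(config.gmt, True):
            problems.append("ssgsea: no GMT and simulate disabled")
    if "ora" in enabled:
        if not available(config.gmt, True):
            problems.append("ora: no GMT and simulate disabled")
        if "deg" not in enabled:
            problems.append("ora: requires the deg stage for the query set")
    if "gsea" in enabled:
        if not available(config.de_table, True):
            problems.append("gsea: no DE table and simulate disabled")
        if not available(config.gmt, True):
            problems.append("gsea: no GMT and simulate disabled")
    if problems:
        raise ValueError("pre-flight validation failed: " + "; ".join(problems))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the enabled stages in dependency order and return the manifest."""
    config.validate()
    _preflight(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=dataclasses.asdict(config))

    # resolved artifact paths (inputs may be replaced by simulate outputs)
    paths = {
        "edge_list": config.edge_list,
        "de_table": config.de_table,
        "expression": config.expression,
        "gmt": config.gmt,
        "target_lists": list(config.target_lists),
    }
    groups = dict(config.groups) or None
    degs: DEGPartition | None = None
    intersection: set[str] | None = None

    def record(name: str, inputs: list[str], outputs: list[str], t0: float) -> None:
        manifest.stages.append(
            {
                "stage": name,
                "inputs": {p: _sha256(Path(p)) for p in inputs if p and Path(p).exists()},
                "outputs": {p: _sha256(Path(p)) for p in outputs},
                "seconds": round(time.monotonic() - t0, 4),
            }
        )

    for stage in _STAGE_ORDER:
        if stage not in config.stages:
            continue
        t0 = time.monotonic()
        logger.info("stage %s starting", stage)

        if stage == "simulate":
            spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
            table, truth = gen_de_table(spec)
            universe = gene_universe(spec.n_genes)
            core_rng = substream(spec.seed, "core_choice")
            core = sorted(truth)[: config.core_size] if truth else sorted(
                universe[i] for i in core_rng.choice(len(universe), size=config.core_size, replace=False)
            )
            targets = gen_target_lists(
                spec.seed, universe, config.n_target_sources, config.per_source_size, core
            )
            set_rng = substream(spec.seed, "gmt_choice")
            planted_members = frozenset(
                sorted(truth)[:50] if len(truth) >= 50
                else (universe[i] for i in set_rng.choice(len(universe), size=50, replace=False))
            )
            decoy = frozenset(
                universe[i] for i in set_rng.choice(len(universe), size=50, replace=False)
            )
            gmt = GeneSetCollection(
                [
                    GeneSet("planted_set", "synthetic planted gene set", planted_members),
                    GeneSet("decoy_set", "synthetic unshifted gene set", decoy),
                ]
            )
            expr = gen_expression(spec, planted_members)
            graph, hub = gen_ppi(spec)

            p = {
                "edge_list": outdir / "network.edges",
                "de_table": outdir / "de_table.tsv",
                "expression": outdir / "expression.tsv",
                "gmt": outdir / "sets.gmt",
            }
            with open(p["edge_list"], "w") as fh:
                for u, v in sorted((min(e), max(e)) for e in graph.edges):
                    fh.write(f"{u} {v}\n")
            table.to_csv(p["de_table"], sep="\t", index=False)
            expr.write_tsv(p["expression"])
            gmt.write_gmt(p["gmt"])
            write_gene_list(truth, outdir / "truth_de_genes.txt")
            write_gene_list([hub], outdir / "truth_hub.txt")
            write_gene_list(core, outdir / "truth_core_targets.txt")
            tpaths = []
            for j, t in enumerate(targets, start=1):
                tp = outdir / f"targets_source{j}.txt"
                write_gene_list(t, tp)
                tpaths.append(str(tp))
            paths.update({k: str(v) for k, v in p.items()})
            paths["target_lists"] = tpaths
            groups = expr.groups
            record("simulate", [], [str(v) for v in p.values()]
                   + [str(outdir / "truth_de_genes.txt"), str(outdir / "truth_hub.txt"),
                      str(outdir / "truth_core_targets.txt")] + tpaths, t0)

        elif stage == "deg":
            table = read_de_table(paths["de_table"], uppercase=config.uppercase_symbols)
            degs = screen_degs(table, config.lfc_cut, config.alpha, config.adjust)
            outs = []
            for name, genes in (("up", degs.up), ("down", degs.down), ("all", degs.all_degs)):
                op = outdir / f"degs_{name}.txt"
                write_gene_list(genes, op)
                outs.append(str(op))
            record("deg", [paths["de_table"]], outs, t0)

        elif stage == "overlap":
            assert degs is not None
            sources = {
                Path(p).stem: read_gene_list(p, uppercase=config.uppercase_symbols)
                for p in paths["target_lists"]
            }
            report = overlap_report(sources, degs, uppercase=config.uppercase_symbols)
            intersection = set(report.intersection_with_degs)
            op1 = outdir / "targets_union.txt"
            op2 = outdir / "targets_in_degs.txt"
            op3 = outdir / "overlap_pairwise.tsv"
            write_gene_list(report.union, op1)
            write_gene_list(report.intersection_with_degs, op2)
            report.pairwise.to_csv(op3, sep="\t")
            record("overlap", list(paths["target_lists"]), [str(op1), str(op2), str(op3)], t0)

        elif stage == "rank":
            graph = read_edge_list(paths["edge_list"], uppercase=config.uppercase_symbols)
            rep = consensus(
                graph, k=config.k, seed=config.seed,
                epc_iters=config.epc_iters, epc_keep=config.epc_keep,
            )
            outs = []
            for m, ranked in rep.per_method.items():
                op = outdir / f"centrality_{m}.tsv"
                write_ranked_scores(ranked, op)
                outs.append(str(op))
            opc = outdir / "consensus_hubs.txt"
            write_gene_list(rep.consensus, opc)
            outs.append(str(opc))
            record("rank", [paths["edge_list"]], outs, t0)

        elif stage == "rwr":
            graph = read_edge_list(paths["edge_list"], uppercase=config.uppercase_symbols)
            sources: frozenset[str] = frozenset()
            if config.source_mode == "given_set":
                sources = frozenset(intersection or [])
                if not sources:
                    raise ValueError("rwr: source_mode given_set but the DEG-target intersection is empty")
                sources = frozenset(s for s in sources if s in graph)
                if not sources:
                    raise ValueError("rwr: no intersection gene is present in the network")
            rcfg = RwrConfig(
                n_walks=config.n_walks, max_steps=config.max_steps,
                restart_prob=config.restart_prob, seed=config.seed,
                source_mode=config.source_mode, sources=sources,
            )
            result = mc_rwr(graph, rcfg)
            op = outdir / "rwr_ranking.tsv"
            write_ranked_scores(result.ranking, op)
            meta = outdir / "rwr_metadata.json"
            with open(meta, "w") as fh:
                json.dump(
                    {
                        "n_walks": rcfg.n_walks, "max_steps": rcfg.max_steps,
                        "restart_prob": rcfg.restart_prob, "seed": rcfg.seed,
                        "source_mode": rcfg.source_mode, "sources": sorted(result.sources),
                        "total_steps_counted": result.total_steps_counted,
                    },
                    fh, indent=2, sort_keys=True,
                )
            record("rwr", [paths["edge_list"]], [str(op), str(meta)], t0)

        elif stage == "ssgsea":
            expr = read_expression(paths["expression"], groups=groups,
                                   uppercase=config.uppercase_symbols)
            sets = read_gmt(paths["gmt"], uppercase=config.uppercase_symbols)
            scores = ssgsea_score(expr, sets, alpha=config.ssgsea_alpha)
            op = outdir / "ssgsea_scores.tsv"
            scores.scores.to_csv(op, sep="\t", index_label="sample")
            outs = [str(op)]
            if expr.groups:
                rows = []
                for term in scores.scores.columns:
                    stat, pval = compare_group_scores(scores, expr.groups, term)
                    rows.append(f"{term}\t{stat:.12g}\t{pval:.12g}")
                op2 = outdir / "ssgsea_group_test.tsv"
                with open(op2, "w") as fh:
                    fh.write("term\tstatistic\tpvalue\n")
                    fh.write("\n".join(rows) + "\n")
                outs.append(str(op2))
            record("ssgsea", [paths["expression"], paths["gmt"]], outs, t0)

        elif stage == "ora":
            assert degs is not None
            sets = read_gmt(paths["gmt"], uppercase=config.uppercase_symbols)
            table = read_de_table(paths["de_table"], uppercase=config.uppercase_symbols)
            universe = set(table["gene"])
            results = ora(set(degs.all_degs), sets, universe)
            op = outdir / "ora_results.tsv"
            with open(op, "w") as fh:
                fh.write("term\toverlap\tset_size\tquery_size\tuniverse_size\tpvalue\tpadj\n")
                for r in results:
                    fh.write(
                        f"{r.term}\t{r.overlap_size}\t{r.set_size}\t{r.query_size}"
                        f"\t{r.universe_size}\t{r.pvalue:.12g}\t{r.padj:.12g}\n"
                    )
            record("ora", [paths["gmt"], paths["de_table"]], [str(op)], t0)

        elif stage == "gsea":
            table = read_de_table(paths["de_table"], uppercase=config.uppercase_symbols)
            sets = read_gmt(paths["gmt"], uppercase=config.uppercase_symbols)
            ranked = rank_by_log2fc(table)
            op = outdir / "gsea_results.tsv"
            with open(op, "w") as fh:
                fh.write("term\tes\tperm_pvalue\tn_perm\n")
                for name in sets:
                    res = gsea_permutation_p(
                        ranked, sets[name].members, n_perm=config.n_perm,
                        seed=config.seed, p=config.gsea_exponent, term=name,
                    )
                    fh.write(f"{res.term}\t{res.es:.12g}\t{res.perm_pvalue:.12g}\t{res.n_perm}\n")
            record("gsea", [paths["de_table"], paths["gmt"]], [str(op)], t0)

        logger.info("stage %s done in %.2fs", stage, time.monotonic() - t0)

    config.to_yaml(outdir / "config.yaml")
    manifest.write(outdir / "manifest.json")
    return manifest
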