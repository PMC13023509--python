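"""Rank network nodes by nine centralities and intersect their top-3 sets.

On the planted-hub network the hub should win every measure; the consensus
(the intersection of the nine tie-expanded top-3 sets) nominates it.
"""

from netprior import SyntheticSpec, consensus, gen_ppi

G, hub = gen_ppi(SyntheticSpec(seed=1))
report = consensus(G, k=3, seed=1)

for method, ranked in report.per_method.items():
    top = ", ".join(f"{g}={s:.3g}" for g, s in list(ranked)[:3])
    print(f"{method:12s} top-3: {top}")
print(f"\nconsensus hubs (k=3, nine methods): {sorted(report.consensus)}")
print(f"planted hub {hub} recovered: {hub in report.consensus}")
# Interpretation: a node that tops all nine topological rankings is a
# robust hub candidate, not an artifact of one centrality's bias.
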