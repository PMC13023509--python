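"""Generate a complete synthetic input bundle with known ground truth.

Builds every artifact the pipeline consumes — a DE summary table with
planted differential genes, a two-group expression matrix with a planted
gene-set shift, a scale-free-like PPI network with a planted hub, and four
overlapping predicted-target lists — and prints what was planted where.
"""

from netprior import SyntheticSpec, gen_de_table, gen_expression, gen_ppi, gen_target_lists, gene_universe

spec = SyntheticSpec(seed=1)

table, truth = gen_de_table(spec)
print(f"DE table: {len(table)} genes, {len(truth)} planted as truly differential")

members = gene_universe(spec.n_genes)[:50]
matrix = gen_expression(spec, members)
print(f"expression: {len(matrix.genes)} genes x {len(matrix.samples)} samples "
      f"(groups {sorted(set(matrix.groups.values()))}), 50-gene set shifted by +{spec.set_shift} in group B")

graph, hub = gen_ppi(spec)
print(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges; "
      f"planted hub {hub} with degree {graph.degree[hub]} "
      f"(next highest {max(d for n, d in graph.degree() if n != hub)})")

core = sorted(truth)[:5]
lists = gen_target_lists(spec.seed, gene_universe(spec.n_genes), n_sources=4,
                         per_source_size=20, core=core)
print(f"target lists: 4 sources of 20, sharing the planted core {core}")
# Interpretation: every downstream stage can now be scored against a known
# answer -- the truth set, the shifted gene set, the hub, and the core.
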