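"""ORA, permutation GSEA and ssGSEA on synthetic data with a planted signal.

Three views of the same planted 50-gene set: hypergeometric
over-representation of the DEG list, the weighted-KS enrichment score on
the full log2FC ranking, and per-sample ssGSEA scores compared 4-vs-4
between groups.
"""

from netprior import (
    SyntheticSpec, compare_group_scores, gen_de_table, gen_expression,
    gene_universe, gsea_permutation_p, ora, rank_by_log2fc, screen_degs,
    ssgsea_score,
)
from netprior.graphio import GeneSet, GeneSetCollection

spec = SyntheticSpec(seed=1, n_genes=1000)
table, truth = gen_de_table(spec)
planted = frozenset(sorted(truth)[:50])
decoy = frozenset(sorted(set(gene_universe(1000)) - truth)[:50])
sets = GeneSetCollection([
    GeneSet("planted_set", "contains 50 truly DE genes", planted),
    GeneSet("decoy_set", "50 null genes", decoy),
])

# 1. ORA of the DEG list
degs = screen_degs(table)
for r in ora(set(degs.all_degs), sets, set(table["gene"])):
    print(f"ORA  {r.term:12s} overlap {r.overlap_size:2d}/{r.set_size}  p={r.pvalue:.3g}  padj={r.padj:.3g}")

# 2. GSEA on the full log2FC-ranked list
ranked = rank_by_log2fc(table)
for name in sets:
    res = gsea_permutation_p(ranked, sets[name].members, n_perm=999, seed=1, term=name)
    print(f"GSEA {name:12s} ES={res.es:+.3f}  perm p={res.perm_pvalue:.3g}")

# 3. ssGSEA with a 4-vs-4 group comparison (planted +5 shift in group B)
matrix = gen_expression(spec, planted)
scores = ssgsea_score(matrix, sets)
for name in sets:
    stat, p = compare_group_scores(scores, matrix.groups, name)
    print(f"ssGSEA {name:12s} Welch t={stat:+.2f}  p={p:.3g}")
# Interpretation: the planted set is significant in all three analyses;
# the decoy set is not.
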