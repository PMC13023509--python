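# Methods

## Problem setting

Given (i) a differential-expression summary contrasting exposed and control
samples, (ii) predicted protein targets of a compound from several
prediction sources, and (iii) an undirected protein–protein interaction
(PPI) network, the pipeline nominates candidate mediator proteins by
intersecting compound targets with disease-associated genes and
prioritizing within the network by topological consensus and random-walk
proximity. Enrichment statistics (ORA, GSEA, ssGSEA) characterize which
pathways carry the signal.

## DEG screening

Adjustment is Benjamini–Hochberg step-up (delegated to
`statsmodels.stats.multitest`): with ascending order statistics
p₍ⱼ₎, adj_i = min_{j≥i} (p₍ⱼ₎·n/j) capped at 1, returned in input order.
A gene is a DEG iff |log2FC| > 0.5 **and** adjusted p < 0.05, both
inequalities strict, so genes exactly on a threshold are excluded. BH is
the default because it is the standard choice of the DESeq2-style
workflows whose summaries this stage consumes; Bonferroni and "none" are
exposed for sensitivity analyses. Rows with missing p-values are dropped
before adjustment (count logged), mirroring upstream independent
filtering. BH's FDR guarantee holds under independence — exactly the
regime the synthetic generator produces; correlated real data may exceed
the nominal level.

## Enrichment statistics

**ORA.** Upper-tail hypergeometric P(X ≥ overlap) with population
|universe|, successes |set ∩ universe|, draws |query| (via
`scipy.stats.hypergeom`); BH across terms; deterministic (pvalue, term)
ordering. Query genes outside the universe are dropped with a warning
rather than silently redefining the universe.

**GSEA.** The weighted Kolmogorov–Smirnov running sum over the full ranked
gene list: hits add |score|^p normalized over hits (p = 1 by default),
misses subtract 1/(N − N_hit); the enrichment score (ES) is the signed
maximum deviation. The ranking metric for DE tables is log2FC descending —
the natural "full gene list" metric — and is configurable. The null is a
gene-label permutation (membership shuffled over list positions, scores
fixed) with the add-one estimate p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1),
which is never zero and is super-uniform by construction. Degenerate case:
a set covering every ranked gene has no misses; ES is defined as +1. If
all hit scores are exactly zero the hit weights fall back to equal
weights.

**ssGSEA.** Per sample, genes are ordered by expression descending (stable
sort, gene-symbol tie-break); rank magnitudes r = N..1 (average ranks at
ties) enter as weights r^α with α = 0.25. The score is
Σᵢ [P_in(i) − P_out(i)], with P_in the weighted ECDF of member positions
and P_out the unweighted ECDF of non-members — an integrated-difference
statistic that depends on ranks only, hence invariant under any strictly
monotone per-sample transform. No cross-sample min–max rescaling is
applied (`ssgsea.normalize = false` in spirit): scores are comparable
across samples of the same matrix through the shared gene list, and
rescaling would couple samples that the group test treats as independent.

**Group comparison.** Two-sided Welch t-test on per-sample scores —
appropriate for small (4-vs-4) continuous scores with no variance-equality
assumption. Two groups of identical constant values return (0, 1); zero
variance with unequal means returns (±inf, 0).

## Target integration

Union with deduplication, then intersection with the DEGs. Gene symbols
are case-sensitive opaque strings; optional uppercasing at read time
(`--uppercase-symbols`) is the explicit harmonization mechanism across
sources with inconsistent capitalization. Regulation direction is carried
through the report as metadata.

## Nine-centrality consensus

Definitions (scores are raw, not normalized, so ties are meaningful):

- **Degree** — edge count.
- **MNC** — size of the largest connected component of the
  neighbor-induced subgraph (node excluded).
- **MCC** — Σ over maximal cliques C containing the node of (|C|−1)!;
  when all such cliques are single edges this equals the degree.
- **EPC** — mean over seeded edge-percolation realizations (each edge kept
  independently with probability 0.5, 1000 iterations by default) of
  |component containing v|/|V|. The draw procedure is fixed and documented
  (edges in sorted order, one uniform per edge per realization) so results
  are auditable and exactly reproducible.
- **Betweenness** — unnormalized shortest-path betweenness (networkx).
- **Stress** — number of shortest paths through the node, over unordered
  endpoint pairs.
- **EcCentricity** — component size divided by the node's eccentricity;
  isolated nodes score 0.
- **Closeness** — harmonic (Σ 1/d), finite on disconnected graphs;
  classic within-component closeness available by flag.
- **Radiality** — Σ over reachable w of (Δ_comp + 1 − d(v,w))/(n − 1) with
  Δ_comp the component diameter and n the graph's node count.

The consensus takes each method's top-k (k = 3) with **tie expansion**: if
the k-th score is tied, all genes at that score are included. This keeps
the consensus deterministic without an arbitrary ordering, at the cost of
occasionally larger top sets; it also reflects that coarse integer-valued
measures (EcCentricity especially) tie frequently on small graphs.
EcCentricity is the measure most likely to exclude a true hub from its
top-3 on small dense graphs, because eccentricity collapses to 2 for many
nodes and ranks within the tie carry no information; this is the dominant
failure mode observed in planted-hub recovery.

## Random walk with restart

Each walk starts at its source; at every step the walker returns to the
source with probability r = 0.1 and otherwise moves to a uniformly random
neighbor (a neighborless node forces a restart). Defaults: 10,000 walks
per source, at most 100 steps per walk. Every occupied position is tallied
— the initial position and post-restart landings included — which makes
the visit-fraction estimate an occupancy measure directly comparable to
the stationary personalized-PageRank vector; dropping those tallies would
bias the estimate away from the source. Restart returns the walker to its
**source** (standard RWR), not to a fresh random node; `source_mode`
exposes three seeding conventions (every node, one random node, a given
gene set such as the target–DEG intersection). Per-source RNG substreams
are derived from (seed, source), so multi-source runs are reproducible and
independent of evaluation order.

`ppr_exact` iterates π ← r·s + (1−r)·Wᵀπ with dangling nodes redirecting
their mass to s, until the L1 change is below 1e-12 (error on
non-convergence). The two-node closed form π_A = r/(r + (1−r)·r·…) =
0.1/0.19 anchors both routes in tests.

## Synthetic data

Defaults: 5000 genes, 10% planted differential with mean |log2FC| 2.0 and
noise SD 0.5; 4-vs-4 samples with a +5 shift of a 50-gene set in group B;
a 20-node preferential-attachment network (2 edges per incoming node) with
12 extra hub edges. Choices, and what they emulate:

- **DE table.** Null genes: log2FC ~ N(0, 0.5), p ~ U(0,1); planted genes:
  log2FC = ±2.0 + N(0, 0.5), p as the two-sided normal tail of the
  effect-to-noise z-score log2FC/0.5, so the realized effect determines the
  p-value as in a real test. A z-score mixture is used instead of
  simulating counts because the pipeline consumes DE *summaries*;
  count-model internals are out of scope. P-values are independent across
  genes — real RNA-seq p-values are correlated, so FDR control shown here
  does not certify control under arbitrary dependence.
- **Expression matrix.** Baseline N(0,1) with an additive group-B shift on
  the planted set. This gives ssGSEA a clean rank signal; it does not
  model library-size effects, mean–variance coupling, or count noise.
- **Network.** Preferential attachment, because PPI degree distributions
  are heavy-tailed; the tens-of-nodes scale matches the subnetworks this
  kind of analysis actually ranks. The hub is planted by adding extra
  edges to a node chosen uniformly among eligible candidates — nodes below
  the current maximum degree, with enough non-neighbors to keep the graph
  simple, and close enough that the wiring overtakes the maximum; the
  extra-edge endpoints are drawn from non-neighbors that cannot tie the
  hub's final degree, so the hub is guaranteed the *unique* maximum.
  Twelve extra edges were chosen because preferential-attachment maxima at
  this scale typically stay at or below degree ~11, leaving a clear margin.
  Rare degenerate realizations (an existing super-hub) make the constraint
  set empty; the generator then raises, and replicate studies skip to the
  next seed (rejection over seeds), which conditions the benchmark on "a
  hub was plantable" without biasing any score.
- **Target lists.** Every pseudo-source contains the planted core; extras
  are drawn without replacement from the rest of the universe,
  independently per source — partial agreement, as real prediction
  databases show.

All generators are pure functions of (seed, parameters); each draws from a
substream hashed from (seed, generator-name), so artifacts are independent
and adding one never perturbs another.

Passing the planted-recovery tests shows the machinery is correct and
calibrated under the generator's idealized assumptions; it does not show
that real expression data or a real PPI network satisfies them.

## Problem sizes and numerical choices

Verification runs use the scales at which the checks are exact or
statistically stable: brute-force centrality oracles on 200 random
connected graphs of ≤ 7 nodes (exhaustive path/clique/subset enumeration
is exact there); percolation expectation by full 2^E enumeration on ≤ 10
edges; recovery and power studies over 100 seeded replicates; FDR over 50
seeded 5000-gene tables; permutation nulls with 199 permutations per
replicate and 200 replicates. Rankings break score ties
lexicographically by gene symbol everywhere, making every output
deterministic. EPC's iteration count (1000) and retention probability
(0.5) are config-exposed and recorded in run metadata, since no standard
fixes them. Floating-point: the weighted GSEA running sum returns to zero
within 1e-9 at the list end; PPR converges to L1 1e-12.

## Known limitations

- Centrality brute-force equality is verified on small graphs; larger
  graphs rely on the same code paths but are not re-verified exhaustively.
- The permutation GSEA p-value has resolution 1/(n_perm + 1); with 199
  permutations the smallest attainable p is 0.005.
- Edge weights (e.g. interaction confidence scores) are read but ignored;
  the network model is unweighted throughout.
- The consensus can be empty on graphs where no node is simultaneously
  top-k under all nine measures; this is reported as an empty set, not an
  error.
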