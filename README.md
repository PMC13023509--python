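# netprior

Network-pharmacology target prioritization in Python: given a compound's
predicted protein targets and a disease's differential-expression signature,
nominate the interaction-network hubs most likely to mediate the compound's
effect.

The package implements the full computational chain used in
compound–disease target nomination studies:

1. **DEG screening** — Benjamini–Hochberg adjustment and the cutoff rule
   |log2FC| > 0.5 with adjusted p < 0.05 (both strict).
2. **Enrichment** — hypergeometric over-representation (ORA) with BH-FDR,
   weighted-KS GSEA with a gene-label permutation null, per-sample ssGSEA
   scores, and a Welch t-test group comparison of those scores.
3. **Target integration** — union of multi-source predicted-target lists
   with deduplication, intersected with the DEGs.
4. **Hub consensus** — nine topological centralities (Degree, MNC, MCC,
   EPC, Betweenness, Stress, EcCentricity, Closeness, Radiality); the
   tie-expanded top-k sets of the nine rankings are intersected.
5. **Random walk with restart** — a Monte Carlo walker (default 10,000
   walks per source, at most 100 steps, restart probability 0.1) whose
   visit fractions rank network proximity, with exact personalized
   PageRank (power iteration) as the closed-form oracle.

A first-class **synthetic-data module** generates every input with planted
ground truth — a DE table with a planted differential fraction, a two-group
expression matrix with a planted gene-set shift, a scale-free-like PPI
network with a planted hub, and overlapping pseudo-source target lists — so
the whole pipeline runs and verifies itself without any external download.

## The statistics at the core

For a source distribution $s$ on the network, the walker obeys

$$\pi = r\,s + (1-r)\,W^{\top}\pi,$$

where $W$ is the row-stochastic uniform-neighbor transition matrix and
$r$ the restart probability; the Monte Carlo visit fractions estimate the
stationary $\pi$ (personalized PageRank). For enrichment, the weighted-KS
running sum increments by $|s_i|^p / \sum_{hits}|s_j|^p$ at member genes and
decrements by $1/(N-N_{hit})$ otherwise; the enrichment score is its signed
maximum deviation. ssGSEA integrates the difference between the weighted
member ECDF and the unweighted non-member ECDF of each sample's expression
ranking. ORA uses the hypergeometric upper tail
$P(X \ge k)$ with population $|U|$, successes $|S \cap U|$, draws $|Q|$.

## Worked example

```bash
python examples/06_rwr_prioritization.py
```

```
top 5 by Monte Carlo visit fraction:
  P19  0.1364   (exact PPR 0.1373)
  P02  0.1297   (exact PPR 0.1302)
  P01  0.1007   (exact PPR 0.1008)
  P06  0.0710   (exact PPR 0.0711)
  P03  0.0612   (exact PPR 0.0614)

total variation MC vs exact: 0.0020
Spearman rank correlation:   0.9992
planted hub P19 in MC top-3: True
```

The walker's occupancy estimate agrees with the exact stationary
distribution to a total variation of 0.002, and both routes place the
planted hub first. The other scripts in `examples/` walk through input
simulation, DEG screening, the three enrichment analyses, target-list
integration and the nine-centrality consensus; `examples/07_full_pipeline.py`
runs every stage through the config-driven orchestrator.

A thin CLI mirrors the library:

```bash
netprior simulate --out sim --seed 1
netprior deg sim/de_table.tsv --out deg_out
netprior rank sim/network.edges --out rank_out --seed 1
netprior rwr sim/network.edges --out rwr.tsv --walks 10000 --restart 0.1
netprior run --outdir full_run --seed 1
```

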