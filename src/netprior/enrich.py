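"""Enrichment statistics: ORA, weighted-KS GSEA, ssGSEA, group comparison.

Four related ways of asking whether a gene set is unusual:

* :func:`ora` — hypergeometric over-representation of a query set against
  annotated sets within a universe, BH-adjusted across terms.
* :func:`gsea_es` / :func:`gsea_permutation_p` — the weighted
  Kolmogorov–Smirnov running-sum enrichment score over a full ranked gene
  list, with a gene-label permutation null.
* :func:`ssgsea_score` — per-sample enrichment scores from the integrated
  difference of the weighted member ECDF and the unweighted non-member ECDF
  over the sample's expression ranking (no cross-sample rescaling).
* :func:`compare_group_scores` — Welch t-test on per-sample scores between
  two groups (e.g. the 4-vs-4 control/exposure design).

Formulas are spelled out in the docstrings; there is no hidden normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .degscreen import bh_adjust
from .graphio import ExpressionMatrix, GeneSetCollection, RankedScores

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "GseaResult",
    "SsgseaScores",
    "ora",
    "gsea_es",
    "gsea_permutation_p",
    "ssgsea_score",
    "compare_group_scores",
    "rank_by_log2fc",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap_size: int
    set_size: int
    query_size: int
    universe_size: int
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        ok = 0 <= self.overlap_size <= min(self.set_size, self.query_size) <= self.universe_size
        if not ok:
            raise ValueError(f"inconsistent counts in {self.term!r}")


@dataclass(frozen=True)
class GseaResult:
    term: str
    es: float
    perm_pvalue: float
    n_perm: int


@dataclass(frozen=True)
class SsgseaScores:
    """Per-(sample, term) enrichment scores; rows = samples, columns = terms."""

    scores: pd.DataFrame
    alpha: float = 0.25


# ---------------------------------------------------------------------------
# over-representation (hypergeometric)
# ---------------------------------------------------------------------------

def ora(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each annotated set.

    For each term, p = P(X >= overlap) with X hypergeometric(population =
    |universe|, successes = |set ∩ universe|, draws = |query|). Query members
    outside the universe are dropped with a warning; sets are intersected
    with the universe before testing. Adjusted p-values are BH across terms;
    results are sorted by (pvalue, term).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        q &= uni
    if not q:
        raise ValueError("empty query (after restriction to the universe)")

    M, n = len(uni), len(q)
    rows = []
    for name in sets:
        members = sets[name].members & uni
        K = len(members)
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    padj = bh_adjust([p for _, _, _, p in rows])
    results = [
        EnrichmentResult(
            term=name,
            overlap_size=k,
            set_size=K,
            query_size=n,
            universe_size=M,
            pvalue=p,
            padj=float(a),
        )
        for (name, k, K, p), a in zip(rows, padj)
    ]
    results.sort(key=lambda r: (r.pvalue, r.term))
    return results


# ---------------------------------------------------------------------------
# GSEA (weighted Kolmogorov–Smirnov running sum)
# ---------------------------------------------------------------------------

def _es_from_mask(scores: np.ndarray, hit: np.ndarray, p: float) -> float:
    """Signed maximum deviation of the running sum for one membership mask.

    Hits increment by |score|^p normalized over hits; misses decrement by
    1/(N - N_hits). With every gene a hit the sum climbs monotonically to 1.
    """
    n = scores.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the ranking")
    if n_hit == n:
        return 1.0  # degenerate: no misses; running sum peaks at 1
    w = np.abs(scores) ** p
    hit_total = w[hit].sum()
    if hit_total == 0.0:  # all hit scores exactly zero: fall back to equal weights
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    else:
        steps = np.where(hit, w / hit_total, -1.0 / (n - n_hit))
        steps[~hit] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_es(ranked: RankedScores, set_members: Iterable[str], p: float = 1.0) -> float:
    """Enrichment score of ``set_members`` on a full ranked gene list.

    ``ranked`` must cover the whole gene list (the statistic is over the
    entire ranking, not a cut); ``p`` is the weight exponent (0 = classic
    unweighted KS, 1 = score-weighted).
    """
    genes = ranked.genes
    scores = np.array([s for _, s in ranked], dtype=float)
    members = set(set_members)
    hit = np.array([g in members for g in genes])
    if not hit.any():
        raise ValueError("gene set has no members in the ranking")
    return _es_from_mask(scores, hit, p)


def gsea_permutation_p(
    ranked: RankedScores,
    set_members: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
    p: float = 1.0,
    term: str = "",
) -> GseaResult:
    """Gene-label permutation test for the enrichment score.

    Membership labels are shuffled over list positions (scores stay put);
    two-sided p = (1 + #{|ES_perm| >= |ES_obs|}) / (n_perm + 1).
    """
    genes = ranked.genes
    scores = np.array([s for _, s in ranked], dtype=float)
    members = set(set_members)
    hit = np.array([g in members for g in genes])
    if not hit.any():
        raise ValueError("gene set has no members in the ranking")
    es_obs = _es_from_mask(scores, hit, p)
    rng = substream(seed, "gsea_perm", term)
    n_extreme = 0
    for _ in range(n_perm):
        perm_hit = np.zeros(hit.size, dtype=bool)
        perm_hit[rng.choice(hit.size, size=int(hit.sum()), replace=False)] = True
        if abs(_es_from_mask(scores, perm_hit, p)) >= abs(es_obs):
            n_extreme += 1
    pval = (1 + n_extreme) / (n_perm + 1)
    return GseaResult(term=term, es=es_obs, perm_pvalue=pval, n_perm=n_perm)


def rank_by_log2fc(table: pd.DataFrame) -> RankedScores:
    """Rank a DE table by log2 fold change, descending (the GSEA metric)."""
    return RankedScores.from_mapping(dict(zip(table["gene"], table["log2fc"])))


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_one(expr: pd.Series, members: set[str], alpha: float) -> float:
    genes = expr.index.to_numpy()
    vals = expr.to_numpy(dtype=float)
    n = vals.size
    # positions: expression descending, gene symbol breaks ties (stable)
    order = np.lexsort((genes, -vals))
    # rank magnitude: highest expression gets rank N; ties share average ranks
    r = stats.rankdata(vals, method="average")
    w = np.abs(r[order]) ** alpha
    hit = np.isin(genes[order], list(members))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the expression matrix")
    if n_hit == n:
        raise ValueError("gene set covers every gene; non-member ECDF undefined")
    p_in = np.cumsum(np.where(hit, w, 0.0)) / w[hit].sum()
    p_out = np.cumsum(~hit) / (n - n_hit)
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
) -> SsgseaScores:
    """Single-sample enrichment scores for every (sample, term) pair.

    Per sample, genes are ranked by expression (descending); rank magnitudes
    ``r = N..1`` enter as weights ``r**alpha``. The score is the integrated
    difference between the weighted ECDF of member positions and the
    unweighted ECDF of non-member positions — a rank statistic, invariant
    under any strictly monotone per-sample transform of the expression
    values. No cross-sample rescaling is applied.
    """
    if len(matrix.genes) < 2:
        raise ValueError("expression matrix needs at least two genes")
    gene_index = set(matrix.genes)
    out = {}
    for name in sets:
        members = sets[name].members & gene_index
        if not members:
            raise ValueError(f"gene set {name!r} has no genes in the expression matrix")
        out[name] = [
            _ssgsea_one(matrix.values[s], members, alpha) for s in matrix.samples
        ]
    scores = pd.DataFrame(out, index=matrix.samples)
    return SsgseaScores(scores=scores, alpha=alpha)


def compare_group_scores(
    scores: SsgseaScores,
    labels: Mapping[str, str],
    term: str | None = None,
) -> tuple[float, float]:
    """Two-sided Welch t-test on per-sample scores between two groups.

    ``labels`` maps sample → group; exactly two groups, each of size >= 2.
    The statistic's sign follows (mean of first group − mean of second) with
    groups taken in sorted label order. Identical groups give (0.0, 1.0).
    """
    if term is None:
        if scores.scores.shape[1] != 1:
            raise ValueError("term must be named when scores cover several terms")
        term = scores.scores.columns[0]
    col = scores.scores[term]
    group_names = sorted(set(labels[s] for s in col.index))
    if len(group_names) != 2:
        raise ValueError(f"expected exactly two groups, found {group_names}")
    a = col[[s for s in col.index if labels[s] == group_names[0]]].to_numpy()
    b = col[[s for s in col.index if labels[s] == group_names[1]]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    if np.allclose(a.var(ddof=1), 0.0) and np.allclose(b.var(ddof=1), 0.0):
        if math.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return (math.inf if a.mean() > b.mean() else -math.inf), 0.0
    stat, pval = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(pval)
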