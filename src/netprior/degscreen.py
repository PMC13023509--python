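"""Differentially-expressed-gene (DEG) screening.

The screen applies the conventional two-part cutoff: |log2 fold change|
strictly greater than a threshold (default 0.5) and multiplicity-adjusted
p-value strictly below a significance level (default 0.05). Adjustment is
Benjamini–Hochberg by default — the default of the DESeq2-style workflows
this stage consumes summaries from — with Bonferroni or no adjustment
available for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["DEGPartition", "bh_adjust", "screen_degs"]

_ADJUST_METHODS = {"bh": "fdr_bh", "bonferroni": "bonferroni"}


@dataclass(frozen=True)
class DEGPartition:
    """Up- and down-regulated gene sets from a DEG screen (disjoint)."""

    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")

    @property
    def all_degs(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i} (p_(j) * n / j) capped at 1, where p_(j) are the
    ascending order statistics; elementwise adjusted >= raw.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    return multipletests(p, method="fdr_bh")[1]


def screen_degs(
    table: pd.DataFrame,
    lfc_cut: float = 0.5,
    alpha: float = 0.05,
    adjust: str = "bh",
) -> DEGPartition:
    """Screen a DE summary table for DEGs.

    A gene is *up* iff ``log2fc > lfc_cut`` and ``padj < alpha``; *down* iff
    ``log2fc < -lfc_cut`` and ``padj < alpha`` — both inequalities strict, so
    a gene sitting exactly on either threshold is excluded. If the table has
    no ``padj`` column it is computed over all rows with ``adjust``
    ("bh", "bonferroni" or "none"). Rows with missing p-values are excluded
    before adjustment (their count is logged), mirroring how independent
    filtering leaves NA p-values in upstream DE tools.
    """
    if table.empty:
        raise ValueError("empty DE table")
    work = table.copy()
    n_na = int(work["pvalue"].isna().sum())
    if n_na:
        logger.info("excluding %d genes with missing p-values before adjustment", n_na)
        work = work.dropna(subset=["pvalue"])
        if work.empty:
            raise ValueError("all p-values missing")
    if "padj" not in work.columns:
        if adjust == "none":
            work = work.assign(padj=work["pvalue"].to_numpy())
        elif adjust in _ADJUST_METHODS:
            adjusted = multipletests(work["pvalue"].to_numpy(), method=_ADJUST_METHODS[adjust])[1]
            work = work.assign(padj=adjusted)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}; expected bh, bonferroni or none")
    sig = work["padj"].to_numpy() < alpha
    lfc = work["log2fc"].to_numpy()
    up = frozenset(work.loc[sig & (lfc > lfc_cut), "gene"])
    down = frozenset(work.loc[sig & (lfc < -lfc_cut), "gene"])
    return DEGPartition(up=up, down=down)
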