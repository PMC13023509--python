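"""Readers and writers for the pipeline's external formats.

The canonical in-memory containers are deliberately plain: a
:class:`networkx.Graph` for the protein–protein interaction (PPI) network, a
:class:`pandas.DataFrame` for differential-expression summary tables, and the
small dataclasses below for gene-set collections, expression matrices and
ranked score lists. Readers validate structure and *reject* malformed input
rather than silently repairing it; recoverable oddities (self-loops, extra
columns on an edge line) are dropped with a logged warning.

Gene symbols are treated as case-sensitive opaque strings. Cross-source
harmonization, when wanted, is explicit: pass ``uppercase=True`` to the
readers (the CLI exposes ``--uppercase-symbols``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "RankedScores",
    "read_edge_list",
    "read_gmt",
    "read_de_table",
    "read_gene_list",
    "read_expression",
    "write_gene_list",
    "write_ranked_scores",
    "read_ranked_scores",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named gene set: GMT name, free-text description, member symbols."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection(Mapping[str, GeneSet]):
    """An ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValueError(f"duplicate gene-set name {s.name!r}")
            self._sets[s.name] = s

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self._sets.values():
                members = "\t".join(sorted(s.members))
                fh.write(f"{s.name}\t{s.description}\t{members}\n")


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with optional two-group labels.

    ``values`` is indexed by gene symbol with one column per sample; the
    optional ``groups`` maps every sample to a group label (e.g. the 4-vs-4
    control/exposure design the downstream score comparison expects).
    """

    values: pd.DataFrame
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.groups is not None:
            missing = set(self.values.columns) - set(self.groups)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass(frozen=True)
class RankedScores:
    """Genes with scores, ordered descending by score.

    Ties are broken lexicographically by gene symbol so that every ranking in
    the pipeline is deterministic.
    """

    items: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    @classmethod
    def from_mapping(cls, scores: Mapping[str, float]) -> "RankedScores":
        genes = list(scores)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in scores")
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(tuple((g, float(s)) for g, s in ordered))

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.items]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in ranking")
        for (_, a), (_, b) in zip(self.items, self.items[1:]):
            if b > a:
                raise ValueError("ranking is not descending")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.items]

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.items)

    def top_k(self, k: int = 3) -> set[str]:
        """The ``k`` highest-scoring genes, expanded across ties.

        If the k-th score is tied, every gene at that score is included, so
        the result may be larger than ``k``.
        """
        if k <= 0:
            raise ValueError("k must be positive")
        if k >= len(self.items):
            return set(self.genes)
        cutoff = self.items[k - 1][1]
        return {g for g, s in self.items if s >= cutoff}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _clean_lines(path: str | Path):
    """Yield (lineno, stripped line) skipping blanks and '#' comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path, uppercase: bool = False) -> nx.Graph:
    """Read an undirected PPI network from a whitespace-delimited edge list.

    One pair of node identifiers per line; extra tokens (e.g. a confidence
    score column) are ignored with a warning because the network is
    unweighted. Self-loop lines are dropped with a warning; duplicate edges
    (in either orientation) collapse.
    """
    G = nx.Graph()
    n_lines = 0
    warned_extra = False
    for lineno, line in _clean_lines(path):
        n_lines += 1
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(
                f"{path}: line {lineno}: expected two node identifiers, got {tokens!r}"
            )
        if len(tokens) > 2 and not warned_extra:
            logger.warning("%s: line %d: ignoring extra tokens beyond the first two", path, lineno)
            warned_extra = True
        u, v = tokens[0], tokens[1]
        if uppercase:
            u, v = u.upper(), v.upper()
        if u == v:
            logger.warning("%s: line %d: dropping self-loop %s-%s", path, lineno, u, v)
            G.add_node(u)
            continue
        G.add_edge(u, v)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge-list file")
    return G


def read_gmt(path: str | Path, uppercase: bool = False) -> GeneSetCollection:
    """Read gene sets in Broad GMT dialect: name TAB description TAB members."""
    sets: list[GeneSet] = []
    for lineno, line in _clean_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT line needs name, description and "
                f"at least one member (found {len(fields)} fields)"
            )
        name, description, *members = fields
        members = [m.strip() for m in members if m.strip()]
        if uppercase:
            members = [m.upper() for m in members]
        if not members:
            raise ValueError(f"{path}: line {lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(name, description, frozenset(members)))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


_DE_REQUIRED = ("gene", "log2fc", "pvalue")


def read_de_table(path: str | Path, uppercase: bool = False) -> pd.DataFrame:
    """Read a differential-expression summary table (TSV with header).

    Required columns: ``gene``, ``log2fc``, ``pvalue``; optional ``padj``.
    Gene symbols must be unique; p-values must lie in [0, 1] (NaN permitted —
    genes with missing p-values are excluded later, at screening time).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    df["gene"] = df["gene"].astype(str)
    if uppercase:
        df["gene"] = df["gene"].str.upper()
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"{path}: duplicate gene symbols: {dupes[:5]}")
    for col in ("pvalue", "padj"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{path}: column {col!r} has values outside [0, 1]")
    keep = ["gene", "log2fc", "pvalue"] + (["padj"] if "padj" in df.columns else [])
    return df[keep].reset_index(drop=True)


def read_gene_list(path: str | Path, uppercase: bool = False) -> set[str]:
    """Read a plain-text gene list, one symbol per line; '#' comments skipped."""
    genes: set[str] = set()
    for _, line in _clean_lines(path):
        symbol = line.split()[0]
        genes.add(symbol.upper() if uppercase else symbol)
    return genes


def read_expression(
    path: str | Path,
    groups: Mapping[str, str] | None = None,
    uppercase: bool = False,
) -> ExpressionMatrix:
    """Read a genes × samples expression TSV (first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if uppercase:
        df.index = df.index.str.upper()
    return ExpressionMatrix(values=df, groups=dict(groups) if groups else None)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def write_ranked_scores(ranked: RankedScores, path: str | Path) -> None:
    """Write a ranking as TSV (rank, gene, score), preserving order."""
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\n")
        for i, (gene, score) in enumerate(ranked, start=1):
            fh.write(f"{i}\t{gene}\t{score:.12g}\n")


def read_ranked_scores(path: str | Path) -> RankedScores:
    df = pd.read_csv(path, sep="\t")
    for col in ("rank", "gene", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    items = tuple((str(g), float(s)) for g, s in zip(df["gene"], df["score"]))
    return RankedScores(items)
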