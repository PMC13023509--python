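"""Target integration: multi-source union and intersection with DEGs.

Predicted compound targets typically come from several databases that
partially agree; this stage deduplicates them into one target set and
intersects it with the disease-associated DEGs, yielding the candidate list
that feeds the network stages. Regulation direction (up/down) is not used by
the intersection itself but is carried in the report as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .degscreen import DEGPartition

__all__ = ["OverlapReport", "union_targets", "intersect_with_degs", "overlap_report"]


@dataclass(frozen=True)
class OverlapReport:
    source_sizes: dict[str, int]
    union: frozenset[str]
    intersection_with_degs: frozenset[str]
    pairwise: pd.DataFrame  # source × source overlap counts
    direction: dict[str, str]  # gene -> "up" | "down" for the intersection

    def __post_init__(self) -> None:
        if not self.intersection_with_degs <= self.union:
            raise ValueError("intersection must be a subset of the union")


def union_targets(sources: Sequence[Iterable[str]], uppercase: bool = False) -> set[str]:
    """Union of target lists after deduplication (and optional uppercasing)."""
    if not sources:
        raise ValueError("at least one target source required")
    out: set[str] = set()
    for src in sources:
        out |= {g.upper() if uppercase else g for g in src}
    if not out:
        raise ValueError("all target sources are empty")
    return out


def intersect_with_degs(targets: Iterable[str], degs: DEGPartition) -> set[str]:
    """Targets that are also DEGs (either direction)."""
    return set(targets) & set(degs.all_degs)


def overlap_report(
    sources: Mapping[str, Iterable[str]],
    degs: DEGPartition,
    uppercase: bool = False,
) -> OverlapReport:
    """Full integration report: sizes, union, DEG intersection, pairwise overlaps."""
    named = {
        name: {g.upper() if uppercase else g for g in members}
        for name, members in sources.items()
    }
    union = union_targets(list(named.values()))
    inter = intersect_with_degs(union, degs)
    names = list(named)
    pairwise = pd.DataFrame(
        [[len(named[a] & named[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    direction = {g: ("up" if g in degs.up else "down") for g in inter}
    return OverlapReport(
        source_sizes={n: len(s) for n, s in named.items()},
        union=frozenset(union),
        intersection_with_degs=frozenset(inter),
        pairwise=pairwise,
        direction=direction,
    )
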