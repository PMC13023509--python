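"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes —
a differential-expression table with a planted fraction of shifted genes and
uniform null p-values, a two-group expression matrix with a planted gene-set
shift, a scale-free-like interaction network with a planted hub, and
overlapping predicted-target lists from several pseudo-sources — so every
downstream stage can be exercised and verified against a known ground truth
without any external download.

All generators are pure functions of their spec (seed included): calling one
twice with the same spec yields byte-identical output. Each generator draws
from its own substream derived from ``(seed, generator-name)``, so generating
one artifact never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .graphio import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "SyntheticSpec",
    "gen_de_table",
    "gen_expression",
    "gen_ppi",
    "gen_target_lists",
    "gene_universe",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the study design the pipeline targets: a 4-vs-4
    two-group expression comparison, a ~10% differentially expressed
    fraction with a 2-unit mean |log2FC| effect, and a small
    preferential-attachment interaction network with one planted hub.
    """

    seed: int = 0
    n_genes: int = 5000
    frac_de: float = 0.1
    effect_mu: float = 2.0
    null_sd: float = 0.5
    n_samples_per_group: int = 4
    set_shift: float = 5.0
    n_nodes: int = 20
    attach_m: int = 2
    hub_extra_edges: int = 12

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_nodes <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("n_genes, n_nodes and n_samples_per_group must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.null_sd <= 0:
            raise ValueError("null_sd must be positive")
        if not 0 < self.attach_m < self.n_nodes:
            raise ValueError("attach_m must satisfy 0 < attach_m < n_nodes")
        if self.hub_extra_edges < 0:
            raise ValueError("hub_extra_edges must be non-negative")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def gene_universe(n_genes: int) -> list[str]:
    """Deterministic synthetic gene symbols G0001..G{n}."""
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def gen_de_table(spec: SyntheticSpec) -> tuple[pd.DataFrame, set[str]]:
    """Generate a DE summary table with a planted set of shifted genes.

    Null genes get ``log2fc ~ Normal(0, null_sd)`` and p-values drawn
    Uniform(0, 1). Planted genes get ``log2fc = ±effect_mu + Normal(0,
    null_sd)`` with random sign, and a p-value computed as the two-sided
    normal tail of the effect-to-noise z-score ``log2fc / null_sd`` — so
    larger realized effects give smaller p-values, as a real test would.
    The adjusted-p column is deliberately absent; it is computed downstream.

    Returns the table and the set of planted (truly DE) gene symbols.
    """
    rng = substream(spec.seed, "de_table")
    genes = gene_universe(spec.n_genes)
    n_de = int(round(spec.frac_de * spec.n_genes))
    planted_idx = rng.choice(spec.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    is_de = np.zeros(spec.n_genes, dtype=bool)
    is_de[planted_idx] = True

    log2fc = rng.normal(0.0, spec.null_sd, size=spec.n_genes)
    signs = rng.choice([-1.0, 1.0], size=spec.n_genes)
    log2fc[is_de] += signs[is_de] * spec.effect_mu

    pvalue = rng.uniform(0.0, 1.0, size=spec.n_genes)
    z = log2fc[is_de] / spec.null_sd
    pvalue[is_de] = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame({"gene": genes, "log2fc": log2fc, "pvalue": pvalue})
    truth = {genes[i] for i in np.flatnonzero(is_de)}
    return table, truth


def gen_expression(spec: SyntheticSpec, gene_set: Iterable[str]) -> ExpressionMatrix:
    """Generate a two-group expression matrix with a planted gene-set shift.

    Baseline values are Normal(0, 1); members of ``gene_set`` are shifted by
    ``+set_shift`` in group B samples only. Sample labels are attached
    (groups "A" and "B", ``n_samples_per_group`` each).
    """
    rng = substream(spec.seed, "expression")
    genes = gene_universe(spec.n_genes)
    members = set(gene_set)
    unknown = members - set(genes)
    if unknown:
        raise ValueError(f"gene_set members outside the synthetic universe: {sorted(unknown)[:5]}")
    k = spec.n_samples_per_group
    samples = [f"A{i+1}" for i in range(k)] + [f"B{i+1}" for i in range(k)]
    values = rng.normal(0.0, 1.0, size=(spec.n_genes, 2 * k))
    member_rows = np.array([g in members for g in genes])
    values[np.ix_(member_rows, np.arange(k, 2 * k))] += spec.set_shift
    df = pd.DataFrame(values, index=genes, columns=samples)
    groups = {s: ("A" if s.startswith("A") else "B") for s in samples}
    return ExpressionMatrix(values=df, groups=groups)


def gen_ppi(spec: SyntheticSpec) -> tuple[nx.Graph, str]:
    """Generate a scale-free-like PPI network with a planted hub.

    The graph grows by preferential attachment (``attach_m`` edges per new
    node), giving the heavy-tailed degree distribution typical of interaction
    networks. A hub is then planted: one node chosen uniformly among the
    non-maximum-degree nodes receives ``hub_extra_edges`` extra edges to
    uniformly chosen non-neighbors, which with the default parameters makes
    it the unique maximum-degree node. Node labels are ``P01..Pnn``.

    Returns the (connected) graph and the hub's symbol.
    """
    rng = substream(spec.seed, "ppi")
    # networkx's BA generator accepts a numpy Generator via seed=
    G0 = nx.barabasi_albert_graph(spec.n_nodes, spec.attach_m, seed=rng)
    width = max(2, len(str(spec.n_nodes)))
    relabel = {i: f"P{i + 1:0{width}d}" for i in G0.nodes}
    G = nx.relabel_nodes(G0, relabel)

    degrees = dict(G.degree())
    max_deg = max(degrees.values())
    n_extra = spec.hub_extra_edges
    # hub candidates: below the current maximum degree AND with enough
    # non-neighbors that the graph stays simple after wiring
    candidates = sorted(
        v for v, d in degrees.items()
        if d < max_deg  # not already the top node
        and (spec.n_nodes - 1 - d) >= n_extra  # enough non-neighbors
        and d + n_extra > max_deg  # wiring can overtake the current maximum
    )
    if not candidates:
        raise ValueError(
            f"hub_extra_edges={n_extra} leaves no eligible hub candidate in a "
            f"{spec.n_nodes}-node graph; the graph cannot stay simple"
        )
    hub = candidates[int(rng.integers(len(candidates)))]
    final_deg = degrees[hub] + n_extra

    # endpoints: uniform over non-neighbors that cannot tie the hub's final
    # degree after gaining one edge, so the hub ends as the UNIQUE maximum
    non_neighbors = sorted(set(G.nodes) - set(G.neighbors(hub)) - {hub})
    pool = [w for w in non_neighbors if degrees[w] + 1 < final_deg]
    if n_extra > len(pool) or final_deg <= max_deg:
        raise ValueError(
            f"hub_extra_edges={n_extra} cannot make {hub} the unique "
            f"maximum-degree node (current maximum {max_deg})"
        )
    chosen = rng.choice(len(pool), size=n_extra, replace=False)
    for i in sorted(chosen):
        G.add_edge(hub, pool[i])
    return G, hub


def gen_target_lists(
    seed: int,
    universe: Sequence[str],
    n_sources: int = 4,
    per_source_size: int = 20,
    core: Iterable[str] = (),
) -> list[set[str]]:
    """Generate overlapping predicted-target lists from pseudo-sources.

    Every source contains ``core`` (the planted true targets); the remaining
    ``per_source_size - |core|`` members are sampled without replacement from
    ``universe ∖ core``, independently per source. Mimics querying several
    target-prediction databases that agree on a handful of genuine targets
    and disagree on the rest.
    """
    core_set = set(core)
    universe = list(dict.fromkeys(universe))
    if not core_set <= set(universe):
        raise ValueError("core must be a subset of the universe")
    if per_source_size < len(core_set):
        raise ValueError("per_source_size smaller than |core|")
    pool = sorted(set(universe) - core_set)
    n_extra = per_source_size - len(core_set)
    if n_extra > len(pool):
        raise ValueError("per_source_size exceeds the universe")
    lists = []
    for j in range(n_sources):
        rng = substream(seed, "targets", j)
        extra_idx = rng.choice(len(pool), size=n_extra, replace=False)
        lists.append(core_set | {pool[i] for i in extra_idx})
    return lists
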