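"""Hub discovery on a PPI network: nine centralities, consensus, and RWR.

Two complementary prioritization routes:

* **Topological consensus** — each node is scored by nine centrality
  measures (Degree, MNC, MCC, EPC, Betweenness, Stress, EcCentricity,
  Closeness, Radiality — the CytoHubba repertoire); the tie-expanded top-k
  sets of the nine rankings are intersected into a consensus hub set.
* **Random walk with restart (RWR)** — a Monte Carlo walker that at each
  step returns to its source with probability ``restart_prob`` and otherwise
  moves to a uniformly random neighbor; node visitation fractions rank
  network proximity. Its stationary counterpart, personalized PageRank
  (PPR), is provided in closed form (power iteration) and serves as the
  exact oracle for the Monte Carlo estimate.

All rankings are deterministic: descending score, lexicographic gene-symbol
tie-break; stochastic scorers (EPC, RWR) draw from substreams derived from
an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from ._rng import substream
from .graphio import RankedScores

__all__ = [
    "CENTRALITY_METHODS",
    "RwrConfig",
    "RwrResult",
    "ConsensusReport",
    "centrality_scores",
    "top_k",
    "consensus",
    "mc_rwr",
    "ppr_exact",
]

CENTRALITY_METHODS = (
    "Degree",
    "MNC",
    "MCC",
    "EPC",
    "Betweenness",
    "Stress",
    "EcCentricity",
    "Closeness",
    "Radiality",
)


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def _degree(G: nx.Graph) -> dict:
    return {v: float(d) for v, d in G.degree()}


def _mnc(G: nx.Graph) -> dict:
    """Maximum neighborhood component: largest connected component of the
    subgraph induced by a node's neighbors (the node itself excluded)."""
    out = {}
    for v in G:
        nbrs = list(G.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = G.subgraph(nbrs)
        out[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return out


def _mcc(G: nx.Graph) -> dict:
    """Maximal clique centrality: sum over maximal cliques C containing the
    node of (|C|-1)!. A node whose maximal cliques are all single edges
    scores its degree (each edge-clique contributes (2-1)! = 1)."""
    out = {v: 0.0 for v in G}
    for clique in nx.find_cliques(G):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += contrib
    return out


def _betweenness(G: nx.Graph) -> dict:
    return {v: float(s) for v, s in nx.betweenness_centrality(G, normalized=False).items()}


def _stress(G: nx.Graph) -> dict:
    """Stress centrality: number of shortest paths passing through a node,
    summed over unordered endpoint pairs s != t with v not an endpoint."""
    nodes = sorted(G.nodes)
    dist: dict = {}
    sigma: dict = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_path_counts(G, s)
    out = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v == s or v == t or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    out[v] += sigma[s][v] * sigma[t][v]
    return out


def _bfs_path_counts(G: nx.Graph, s) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts from s."""
    dist = {s: 0}
    sigma = {s: 1.0}
    frontier = [s]
    d = 0
    while frontier:
        d += 1
        nxt: dict = {}
        for u in frontier:
            for w in G.neighbors(u):
                if w in dist:
                    if dist[w] == d:
                        sigma[w] += sigma[u]
                        continue
                    continue
                nxt.setdefault(w, 0.0)
                nxt[w] += sigma[u]
        for w, c in nxt.items():
            dist[w] = d
            sigma[w] = c
        frontier = list(nxt)
    return dist, sigma


def _eccentricity_score(G: nx.Graph) -> dict:
    """EcCentricity: component size divided by the node's eccentricity within
    its component; an isolated node scores 0."""
    out = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if len(comp) == 1:
            out.update({v: 0.0 for v in comp})
            continue
        ecc = nx.eccentricity(sub)
        out.update({v: len(comp) / ecc[v] for v in comp})
    return out


def _closeness(G: nx.Graph, variant: str = "harmonic") -> dict:
    """Harmonic closeness (sum of reciprocal distances; unreachable nodes
    contribute 0) by default — finite on disconnected graphs. The classic
    within-component variant is available as ``variant='classic'``."""
    if variant == "harmonic":
        return {v: float(s) for v, s in nx.harmonic_centrality(G).items()}
    if variant != "classic":
        raise ValueError("closeness variant must be 'harmonic' or 'classic'")
    out = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        for v in comp:
            if len(comp) == 1:
                out[v] = 0.0
            else:
                total = sum(nx.single_source_shortest_path_length(sub, v).values())
                out[v] = (len(comp) - 1) / total
    return out


def _radiality(G: nx.Graph) -> dict:
    """Radiality: sum over reachable w of (diameter + 1 - d(v, w)) scaled by
    1/(n-1), with the diameter taken within the node's component and n the
    graph's node count."""
    n = G.number_of_nodes()
    out = {}
    if n <= 1:
        return {v: 0.0 for v in G}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if len(comp) == 1:
            out.update({v: 0.0 for v in comp})
            continue
        diam = nx.diameter(sub)
        for v in comp:
            dists = nx.single_source_shortest_path_length(sub, v)
            total = sum(diam + 1 - d for w, d in dists.items() if w != v)
            out[v] = total / (n - 1)
    return out


def _epc(G: nx.Graph, iters: int, keep: float, seed: int) -> dict:
    """Edge percolated component: mean over seeded percolation realizations
    of |component containing v| / |V|, retaining each edge independently
    with probability ``keep``.

    Draw procedure (fixed so results are reproducible and auditable): edges
    taken in sorted order; one uniform per edge per realization from the
    substream (seed, "epc"); edge kept iff uniform < keep.
    """
    if not 0.0 <= keep <= 1.0:
        raise ValueError("epc_keep must lie in [0, 1]")
    nodes = sorted(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = sorted((min(u, v), max(u, v)) for u, v in G.edges)
    rng = substream(seed, "epc")
    acc = np.zeros(n)
    for _ in range(iters):
        u01 = rng.random(len(edges))
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (a, b), u in zip(edges, u01):
            if u < keep:
                ra, rb = find(idx[a]), find(idx[b])
                if ra != rb:
                    parent[ra] = rb
        roots = [find(i) for i in range(n)]
        sizes = np.bincount(roots, minlength=n)
        acc += sizes[roots] / n
    return {v: acc[idx[v]] / iters for v in nodes}


def centrality_scores(
    graph: nx.Graph,
    method: str,
    epc_iters: int = 1000,
    epc_keep: float = 0.5,
    seed: int = 0,
    closeness_variant: str = "harmonic",
) -> RankedScores:
    """Score every node of ``graph`` by one of the nine centrality methods."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if method == "Degree":
        scores = _degree(graph)
    elif method == "MNC":
        scores = _mnc(graph)
    elif method == "MCC":
        scores = _mcc(graph)
    elif method == "EPC":
        scores = _epc(graph, epc_iters, epc_keep, seed)
    elif method == "Betweenness":
        scores = _betweenness(graph)
    elif method == "Stress":
        scores = _stress(graph)
    elif method == "EcCentricity":
        scores = _eccentricity_score(graph)
    elif method == "Closeness":
        scores = _closeness(graph, closeness_variant)
    elif method == "Radiality":
        scores = _radiality(graph)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {CENTRALITY_METHODS}")
    return RankedScores.from_mapping(scores)


def top_k(scores: RankedScores, k: int = 3) -> set[str]:
    """Tie-expanded top-k (see :meth:`RankedScores.top_k`)."""
    return scores.top_k(k)


@dataclass(frozen=True)
class ConsensusReport:
    """Per-method rankings, tie-expanded top-k sets and their intersection."""

    per_method: dict[str, RankedScores]
    top_sets: dict[str, frozenset[str]]
    consensus: frozenset[str]
    k: int

    def __post_init__(self) -> None:
        for name, s in self.top_sets.items():
            if not self.consensus <= s:
                raise ValueError(f"consensus not contained in top set of {name}")


def consensus(
    graph: nx.Graph,
    methods: Sequence[str] = CENTRALITY_METHODS,
    k: int = 3,
    seed: int = 0,
    epc_iters: int = 1000,
    epc_keep: float = 0.5,
) -> ConsensusReport:
    """Intersect the tie-expanded top-k node sets of the chosen centralities.

    The result is invariant to method evaluation order (pure intersection of
    per-method sets).
    """
    per_method = {
        m: centrality_scores(graph, m, epc_iters=epc_iters, epc_keep=epc_keep, seed=seed)
        for m in methods
    }
    top_sets = {m: frozenset(top_k(r, k)) for m, r in per_method.items()}
    cons: set[str] = set(graph.nodes)
    for s in top_sets.values():
        cons &= s
    return ConsensusReport(per_method=per_method, top_sets=top_sets, consensus=frozenset(cons), k=k)


# ---------------------------------------------------------------------------
# random walk with restart
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RwrConfig:
    """Monte Carlo RWR parameters. Defaults: 10,000 walks per source, at
    most 100 steps per walk, restart probability 0.1."""

    n_walks: int = 10_000
    max_steps: int = 100
    restart_prob: float = 0.1
    seed: int = 0
    source_mode: str = "each_node"  # each_node | single_random | given_set
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob < 1.0:
            raise ValueError("restart_prob must lie strictly in (0, 1)")
        if self.n_walks <= 0 or self.max_steps < 0:
            raise ValueError("n_walks must be positive and max_steps non-negative")
        if self.source_mode not in ("each_node", "single_random", "given_set"):
            raise ValueError("source_mode must be each_node, single_random or given_set")


@dataclass(frozen=True)
class RwrResult:
    visit_fraction: dict[str, float]
    ranking: RankedScores
    total_steps_counted: int
    sources: tuple[str, ...]


def _resolve_sources(graph: nx.Graph, config: RwrConfig) -> list[str]:
    nodes = sorted(graph.nodes)
    if config.source_mode == "each_node":
        return nodes
    if config.source_mode == "single_random":
        rng = substream(config.seed, "rwr_source_choice")
        return [nodes[int(rng.integers(len(nodes)))]]
    missing = set(config.sources) - set(nodes)
    if missing:
        raise ValueError(f"sources not in graph: {sorted(missing)[:5]}")
    if not config.sources:
        raise ValueError("empty source set")
    return sorted(config.sources)


def mc_rwr(graph: nx.Graph, config: RwrConfig) -> RwrResult:
    """Monte Carlo random walk with restart.

    Each walk starts at its source node. At every step the walker returns to
    its source with probability ``restart_prob``, otherwise it moves to a
    uniformly random neighbor of its current node (a neighborless node forces
    a restart). Every occupied position is tallied — the start and
    post-restart positions included — so the visit fractions estimate the
    occupancy measure that personalized PageRank computes exactly. Each
    source draws from its own substream of ``(seed, source)``, making
    multi-source runs reproducible and order-independent.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    # flattened adjacency for vectorized neighbor draws
    deg = np.zeros(n, dtype=np.int64)
    adj_chunks = []
    offsets = np.zeros(n + 1, dtype=np.int64)
    for i, v in enumerate(nodes):
        nbrs = sorted(graph.neighbors(v))
        deg[i] = len(nbrs)
        offsets[i + 1] = offsets[i] + len(nbrs)
        adj_chunks.extend(idx[w] for w in nbrs)
    adj = np.array(adj_chunks, dtype=np.int64) if adj_chunks else np.zeros(0, dtype=np.int64)

    sources = _resolve_sources(graph, config)
    tally = np.zeros(n, dtype=np.int64)
    for src in sources:
        rng = substream(config.seed, "rwr", src)
        s = idx[src]
        pos = np.full(config.n_walks, s, dtype=np.int64)
        tally[s] += config.n_walks  # initial occupancy
        for _ in range(config.max_steps):
            restart = rng.random(config.n_walks) < config.restart_prob
            u = rng.random(config.n_walks)
            d = deg[pos]
            stuck = d == 0
            nbr_idx = np.floor(u * np.maximum(d, 1)).astype(np.int64)
            if adj.size:
                flat = offsets[pos] + np.minimum(nbr_idx, np.maximum(d - 1, 0))
                moved = adj[np.minimum(flat, adj.size - 1)]  # stuck entries overwritten below
            else:
                moved = pos
            pos = np.where(restart | stuck, s, moved)
            tally += np.bincount(pos, minlength=n)
    total = int(tally.sum())
    frac = tally / total
    visit = {v: float(frac[idx[v]]) for v in nodes}
    return RwrResult(
        visit_fraction=visit,
        ranking=RankedScores.from_mapping(visit),
        total_steps_counted=total,
        sources=tuple(sources),
    )


def ppr_exact(
    graph: nx.Graph,
    source: str | Iterable[str] | Mapping[str, float],
    restart_prob: float = 0.1,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> RankedScores:
    """Personalized PageRank by power iteration — the exact RWR occupancy.

    Iterates pi <- r*s + (1-r)*W^T pi with W the row-stochastic
    uniform-neighbor transition matrix; dangling (neighborless) nodes
    redirect all their mass to the source distribution s. ``source`` may be
    a single node, an iterable of nodes (uniform over them) or an explicit
    probability mapping. Stops when the L1 change drops below ``tol``.
    """
    if not 0.0 < restart_prob < 1.0:
        raise ValueError("restart_prob must lie strictly in (0, 1)")
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)

    s = np.zeros(n)
    if isinstance(source, str):
        s[idx[source]] = 1.0
    elif isinstance(source, Mapping):
        for v, w in source.items():
            s[idx[v]] = w
        if not math.isclose(s.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("source distribution must sum to 1")
    else:
        src = sorted(set(source))
        if not src:
            raise ValueError("empty source set")
        for v in src:
            s[idx[v]] = 1.0 / len(src)

    A = nx.to_numpy_array(graph, nodelist=nodes)
    deg = A.sum(axis=1)
    dangling = deg == 0
    W = np.zeros_like(A)
    nz = ~dangling
    W[nz] = A[nz] / deg[nz, None]

    pi = s.copy()
    for _ in range(max_iter):
        dangling_mass = pi[dangling].sum()
        new = restart_prob * s + (1 - restart_prob) * (W.T @ pi + dangling_mass * s)
        delta = np.abs(new - pi).sum()
        pi = new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"power iteration did not converge; residual {delta:.3e}")
    pi = pi / pi.sum()
    return RankedScores.from_mapping({v: float(pi[idx[v]]) for v in nodes})
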