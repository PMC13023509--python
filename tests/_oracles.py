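"""Independent brute-force oracles used to verify the implementation.

Everything here is written from first principles — exhaustive enumeration of
subsets, simple paths and percolation subsets — and deliberately shares no
code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import networkx as nx
import numpy as np

from netprior._rng import substream


# ---------------------------------------------------------------------------
# graph helpers
# ---------------------------------------------------------------------------

def random_connected_graph(seed: int, max_nodes: int = 7) -> nx.Graph:
    """A seeded random connected graph with 2..max_nodes string-labelled nodes."""
    rng = np.random.default_rng(seed)
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.3, 0.9))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(G):
            return nx.relabel_nodes(G, {i: f"N{i}" for i in G.nodes})


def _all_pairs_dist(G: nx.Graph) -> dict:
    """Floyd–Warshall distances by hand."""
    nodes = list(G.nodes)
    INF = math.inf
    d = {(u, v): (0 if u == v else (1 if G.has_edge(u, v) else INF))
         for u in nodes for v in nodes}
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _all_shortest_paths(G: nx.Graph, s, t) -> list[tuple]:
    """All shortest s-t paths by exhaustive simple-path enumeration."""
    if s == t:
        return [(s,)]
    paths = []
    best = math.inf

    def extend(path):
        nonlocal best
        last = path[-1]
        if last == t:
            if len(path) < best:
                best = len(path)
            paths.append(tuple(path))
            return
        if len(path) > best:
            return
        for w in G.neighbors(last):
            if w not in path:
                extend(path + [w])

    extend([s])
    shortest = [p for p in paths if len(p) == best]
    return shortest


# ---------------------------------------------------------------------------
# centrality oracles
# ---------------------------------------------------------------------------

def degree_oracle(G):
    return {v: float(sum(1 for _ in G.neighbors(v))) for v in G}


def mnc_oracle(G):
    out = {}
    for v in G:
        nbrs = set(G.neighbors(v))
        best = 0
        seen = set()
        for start in nbrs:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for w in G.neighbors(u):
                    if w in nbrs and w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen |= comp
            best = max(best, len(comp))
        out[v] = float(best)
    return out


def mcc_oracle(G):
    """Sum of (|C|-1)! over maximal cliques containing each node, with cliques
    found by exhaustive subset enumeration."""
    nodes = list(G.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(G.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    out = {v: 0.0 for v in nodes}
    for c in maximal:
        for v in c:
            out[v] += math.factorial(len(c) - 1)
    return out


def betweenness_oracle(G):
    nodes = list(G.nodes)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        sps = _all_shortest_paths(G, s, t)
        if not sps:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sps if v in p)
            out[v] += through / len(sps)
    return out


def stress_oracle(G):
    nodes = list(G.nodes)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        sps = _all_shortest_paths(G, s, t)
        for v in nodes:
            if v in (s, t):
                continue
            out[v] += sum(1 for p in sps if v in p)
    return out


def eccentricity_oracle(G):
    d = _all_pairs_dist(G)
    out = {}
    for v in G:
        comp = [w for w in G if d[v, w] < math.inf]
        ecc = max(d[v, w] for w in comp)
        out[v] = 0.0 if ecc == 0 else len(comp) / ecc
    return out


def harmonic_closeness_oracle(G):
    d = _all_pairs_dist(G)
    return {
        v: sum(1.0 / d[v, w] for w in G if w != v and d[v, w] < math.inf)
        for v in G
    }


def radiality_oracle(G):
    d = _all_pairs_dist(G)
    n = len(G)
    out = {}
    comps = []
    unseen = set(G.nodes)
    while unseen:
        v = unseen.pop()
        comp = {w for w in G if d[v, w] < math.inf}
        comps.append(comp)
        unseen -= comp
    for comp in comps:
        diam = max((d[u, w] for u in comp for w in comp), default=0)
        for v in comp:
            if len(comp) == 1 or n <= 1:
                out[v] = 0.0
            else:
                out[v] = sum(diam + 1 - d[v, w] for w in comp if w != v) / (n - 1)
    return out


def epc_same_bits_oracle(G, iters: int, keep: float, seed: int):
    """EPC re-implemented independently (own component search), consuming the
    documented Bernoulli draw procedure: edges in sorted order, one uniform
    per edge per realization from substream (seed, 'epc')."""
    nodes = sorted(G.nodes)
    edges = sorted((min(u, v), max(u, v)) for u, v in G.edges)
    rng = substream(seed, "epc")
    acc = {v: 0.0 for v in nodes}
    for _ in range(iters):
        u01 = rng.random(len(edges))
        kept = [e for e, u in zip(edges, u01) if u < keep]
        adj = defaultdict(set)
        for a, b in kept:
            adj[a].add(b)
            adj[b].add(a)
        seen = set()
        for v in nodes:
            if v in seen:
                continue
            comp = {v}
            stack = [v]
            while stack:
                x = stack.pop()
                for w in adj[x]:
                    if w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen |= comp
            for w in comp:
                acc[w] += len(comp) / len(nodes)
    return {v: acc[v] / iters for v in nodes}


def epc_exact_expectation(G, keep: float):
    """Exact E[|comp(v)|/|V|] by enumerating all 2^E edge subsets."""
    nodes = sorted(G.nodes)
    edges = sorted((min(u, v), max(u, v)) for u, v in G.edges)
    m = len(edges)
    out = {v: 0.0 for v in nodes}
    for mask in range(2**m):
        prob = 1.0
        adj = defaultdict(set)
        for j, (a, b) in enumerate(edges):
            if mask >> j & 1:
                prob *= keep
                adj[a].add(b)
                adj[b].add(a)
            else:
                prob *= 1 - keep
        seen = set()
        for v in nodes:
            if v in seen:
                continue
            comp = {v}
            stack = [v]
            while stack:
                x = stack.pop()
                for w in adj[x]:
                    if w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen |= comp
            for w in comp:
                out[w] += prob * len(comp) / len(nodes)
    return out


CENTRALITY_ORACLES = {
    "Degree": degree_oracle,
    "MNC": mnc_oracle,
    "MCC": mcc_oracle,
    "Betweenness": betweenness_oracle,
    "Stress": stress_oracle,
    "EcCentricity": eccentricity_oracle,
    "Closeness": harmonic_closeness_oracle,
    "Radiality": radiality_oracle,
}


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def bh_oracle(pvalues):
    """Benjamini–Hochberg step-up by direct hand computation."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adj[i] = running_min
    return adj


def hypergeom_tail_by_enumeration(M: int, K: int, n: int, k: int) -> float:
    """P(|Q ∩ S| >= k) over all size-n subsets Q of a size-M universe with a
    fixed size-K set S, by exhaustive enumeration."""
    universe = list(range(M))
    S = set(range(K))
    total = 0
    hits = 0
    for Q in itertools.combinations(universe, n):
        total += 1
        if len(S & set(Q)) >= k:
            hits += 1
    return hits / total


def gsea_es_reference(scores, hit_flags, p):
    """Running-sum ES by an explicit step-by-step loop."""
    n = len(scores)
    n_hit = sum(hit_flags)
    if n_hit == n:
        return 1.0
    denom = sum(abs(s) ** p for s, h in zip(scores, hit_flags) if h)
    running = 0.0
    best = 0.0
    for s, h in zip(scores, hit_flags):
        if h:
            running += (abs(s) ** p / denom) if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best
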