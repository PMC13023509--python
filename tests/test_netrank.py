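import networkx as nx
import numpy as np
import pytest
from scipy.stats import spearmanr

from netprior import (
    CENTRALITY_METHODS,
    RwrConfig,
    SyntheticSpec,
    centrality_scores,
    consensus,
    gen_ppi,
    mc_rwr,
    ppr_exact,
    top_k,
)
from netprior.graphio import RankedScores

from _oracles import (
    CENTRALITY_ORACLES,
    epc_exact_expectation,
    epc_same_bits_oracle,
    random_connected_graph,
)


class TestCentralities:
    def test_star_degree(self, star5):
        scores = centrality_scores(star5, "Degree").scores
        assert scores["C"] == 4 and all(scores[f"L{i}"] == 1 for i in range(1, 5))

    def test_triangle_mcc(self, triangle):
        scores = centrality_scores(triangle, "MCC").scores
        assert all(v == 2.0 for v in scores.values())  # (3-1)! per node

    def test_path_betweenness_and_stress(self, path3):
        b = centrality_scores(path3, "Betweenness").scores
        s = centrality_scores(path3, "Stress").scores
        assert b == {"B": 1.0, "A": 0.0, "C": 0.0}
        assert s == {"B": 1.0, "A": 0.0, "C": 0.0}

    def test_star_mnc_center_is_one(self, star5):
        scores = centrality_scores(star5, "MNC").scores
        assert scores["C"] == 1.0  # leaves induce an edgeless subgraph

    def test_epc_keep_one_equals_component_fraction(self):
        G = nx.Graph([("A", "B"), ("C", "D"), ("D", "E")])
        scores = centrality_scores(G, "EPC", epc_iters=10, epc_keep=1.0, seed=0).scores
        assert scores["A"] == pytest.approx(2 / 5)
        assert scores["C"] == pytest.approx(3 / 5)

    def test_unknown_method_lists_the_nine(self, star5):
        with pytest.raises(ValueError, match="MCC"):
            centrality_scores(star5, "PageRank")

    @pytest.mark.parametrize("method", sorted(CENTRALITY_ORACLES))
    def test_matches_brute_force_on_random_graphs(self, method):
        """Each deterministic centrality equals its exhaustive-enumeration
        oracle on seeded random connected graphs of up to 7 nodes."""
        for seed in range(40):
            G = random_connected_graph(seed)
            got = centrality_scores(G, method).scores
            expected = CENTRALITY_ORACLES[method](G)
            assert got == pytest.approx(expected, abs=1e-9), (method, seed)

    def test_epc_same_bits_oracle_equality(self):
        for seed in range(10):
            G = random_connected_graph(seed)
            got = centrality_scores(G, "EPC", epc_iters=40, epc_keep=0.5, seed=seed).scores
            expected = epc_same_bits_oracle(G, iters=40, keep=0.5, seed=seed)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_epc_estimates_exact_expectation(self):
        """MC EPC approaches the 2^E-enumeration expectation."""
        G = nx.Graph([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        exact = epc_exact_expectation(G, keep=0.5)
        got = centrality_scores(G, "EPC", epc_iters=4000, epc_keep=0.5, seed=1).scores
        for v in G:
            assert got[v] == pytest.approx(exact[v], abs=0.03)


class TestTopKConsensus:
    def test_top_k_examples(self):
        r = RankedScores.from_mapping({"A": 3, "B": 2, "C": 1, "D": 0})
        assert top_k(r, 3) == {"A", "B", "C"}

    def test_star_consensus_contains_center(self, star5):
        rep = consensus(star5, k=1, seed=0)
        assert "C" in rep.consensus

    def test_edgeless_graph_total_tie(self):
        G = nx.Graph()
        G.add_nodes_from(["A", "B", "C"])
        rep = consensus(G, k=3, seed=0)
        assert rep.consensus == {"A", "B", "C"}

    def test_consensus_invariant_to_method_order(self, star5):
        a = consensus(star5, methods=list(CENTRALITY_METHODS), k=2, seed=3)
        b = consensus(star5, methods=list(reversed(CENTRALITY_METHODS)), k=2, seed=3)
        assert a.consensus == b.consensus

    def test_planted_hub_in_consensus(self):
        G, hub = gen_ppi(SyntheticSpec(seed=5))
        rep = consensus(G, k=3, seed=5, epc_iters=200)
        assert hub in rep.consensus


class TestMcRwr:
    def test_isolated_node_all_mass(self):
        G = nx.Graph()
        G.add_node("X")
        res = mc_rwr(G, RwrConfig(n_walks=10, max_steps=20, seed=0))
        assert res.visit_fraction == {"X": 1.0}

    def test_two_node_closed_form(self):
        G = nx.Graph([("A", "B")])
        res = mc_rwr(G, RwrConfig(seed=1, source_mode="given_set", sources=frozenset({"A"})))
        assert res.visit_fraction["A"] == pytest.approx(0.1 / 0.19, abs=0.02)

    def test_triangle_symmetry(self):
        G = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        res = mc_rwr(G, RwrConfig(seed=2, source_mode="given_set", sources=frozenset({"A"})))
        assert abs(res.visit_fraction["B"] - res.visit_fraction["C"]) < 0.02

    def test_visit_fractions_sum_to_one(self):
        G, _ = gen_ppi(SyntheticSpec(seed=3))
        res = mc_rwr(G, RwrConfig(n_walks=500, max_steps=30, seed=3))
        assert sum(res.visit_fraction.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(res.visit_fraction) == set(G.nodes)

    def test_deterministic_and_source_order_independent(self):
        G, _ = gen_ppi(SyntheticSpec(seed=4))
        cfg = RwrConfig(n_walks=200, max_steps=20, seed=9)
        assert mc_rwr(G, cfg).visit_fraction == mc_rwr(G, cfg).visit_fraction

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RwrConfig(restart_prob=0.0)
        G = nx.Graph([("A", "B")])
        with pytest.raises(ValueError):
            mc_rwr(G, RwrConfig(source_mode="given_set", sources=frozenset()))

    def test_walk_count_monotonicity(self):
        """More walks cannot worsen agreement with the exact distribution
        (averaged over seeds)."""
        G, _ = gen_ppi(SyntheticSpec(seed=0))
        exact = ppr_exact(G, sorted(G.nodes), 0.1).scores
        ex = np.array([exact[n] for n in sorted(G.nodes)])

        def tv(n_walks, seed):
            res = mc_rwr(G, RwrConfig(n_walks=n_walks, max_steps=100, seed=seed))
            mc = np.array([res.visit_fraction[n] for n in sorted(G.nodes)])
            return 0.5 * np.abs(mc - ex).sum()

        coarse = np.mean([tv(200, s) for s in range(10)])
        fine = np.mean([tv(20_000, s) for s in range(10)])
        assert fine <= coarse


class TestPprExact:
    def test_two_node_closed_form(self):
        G = nx.Graph([("A", "B")])
        r = ppr_exact(G, "A", restart_prob=0.1)
        assert r.scores["A"] == pytest.approx(0.1 / 0.19, abs=1e-9)
        assert r.scores["B"] == pytest.approx(0.09 / 0.19, abs=1e-9)

    def test_restart_prob_near_one_returns_source(self):
        G = nx.Graph([("A", "B"), ("B", "C")])
        r = ppr_exact(G, "A", restart_prob=0.999999)
        assert r.scores["A"] == pytest.approx(1.0, abs=1e-5)

    def test_complete_graph_uniform_source_uniform(self):
        G = nx.complete_graph(5)
        G = nx.relabel_nodes(G, {i: f"N{i}" for i in G.nodes})
        r = ppr_exact(G, sorted(G.nodes), restart_prob=0.1)
        for v in G:
            assert r.scores[v] == pytest.approx(0.2, abs=1e-10)

    def test_dangling_node_redirects_to_source(self):
        G = nx.Graph([("A", "B")])
        G.add_node("Z")  # isolated: all its mass returns to the source
        r = ppr_exact(G, "A", restart_prob=0.1)
        assert r.scores["Z"] == pytest.approx(0.0, abs=1e-9)
        assert sum(r.scores.values()) == pytest.approx(1.0)

    def test_mc_converges_to_exact(self):
        """TV <= 0.05 and Spearman >= 0.9 between the Monte Carlo and exact
        rankings on planted-hub graphs."""
        for seed in (0, 1):
            G, hub = gen_ppi(SyntheticSpec(seed=seed))
            nodes = sorted(G.nodes)
            res = mc_rwr(G, RwrConfig(seed=seed))
            exact = ppr_exact(G, nodes, 0.1)
            mc = np.array([res.visit_fraction[n] for n in nodes])
            ex = np.array([exact.scores[n] for n in nodes])
            assert 0.5 * np.abs(mc - ex).sum() <= 0.05
            assert spearmanr(mc, ex).statistic >= 0.9
            assert res.ranking.top_k(3) == exact.top_k(3)
            assert hub in exact.top_k(3)
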