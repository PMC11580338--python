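import math

import networkx as nx
import numpy as np
import pytest

from cooccursig.network import (
    betweenness,
    centrality_report,
    cpm_quality,
    default_resolution,
    global_species,
    hub_scores,
    leiden_cpm,
    top_k,
)
from oracles import exhaustive_cpm_optimum, naive_betweenness


def graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestGlobalAndResolution:
    def test_global_species_is_node_set(self):
        g = graph([("a", "b"), ("c", "d")])
        assert global_species(g) == {"a", "b", "c", "d"}
        assert global_species(nx.Graph()) == set()

    def test_four_cycle_resolution(self):
        g = nx.cycle_graph(4)
        assert default_resolution(g) == pytest.approx(2 / 3)

    def test_triangle_resolution(self):
        assert default_resolution(nx.complete_graph(3)) == pytest.approx(1.0)

    @pytest.mark.parametrize("n, k", [(6, 3), (8, 5), (10, 4)])
    def test_regular_graph_closed_form(self, n, k):
        g = nx.random_regular_graph(k, n, seed=1)
        assert default_resolution(g) == pytest.approx(k / (n - 1))

    def test_single_node_rejected(self):
        g = graph([], nodes=["a"])
        with pytest.raises(ValueError):
            default_resolution(g)


class TestCPMQuality:
    def test_triangle_one_cluster(self):
        g = nx.complete_graph(3)
        one = {n: 1 for n in g}
        assert cpm_quality(g, one, gamma=1.0) == pytest.approx(0.0)
        assert cpm_quality(g, one, gamma=0.5) == pytest.approx(1.5)

    def test_singletons_score_zero(self):
        g = nx.gnp_random_graph(7, 0.5, seed=3)
        singles = {n: i for i, n in enumerate(g)}
        for gamma in (0.2, 0.7, 1.3):
            assert cpm_quality(g, singles, gamma) == 0.0


class TestLeiden:
    def test_two_triangles_recovered(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        part = leiden_cpm(g, gamma=0.5)
        assert part.quality == pytest.approx(3.0)
        clusters = {frozenset(m) for m in part.clusters().values()}
        assert clusters == {frozenset("abc"), frozenset("xyz")}

    def test_two_cliques_one_bridge(self):
        g = nx.Graph()
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        for group in (left, right):
            g.add_edges_from(
                (a, b) for i, a in enumerate(group) for b in group[i + 1 :]
            )
        g.add_edge("l0", "r0")
        part = leiden_cpm(g, gamma=0.9)
        clusters = {frozenset(m) for m in part.clusters().values()}
        assert clusters == {frozenset(left), frozenset(right)}

    def test_components_never_merged(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d"), ("e", "f")])
        part = leiden_cpm(g, gamma=0.5)
        for u, v in [("a", "c"), ("a", "e"), ("c", "e")]:
            assert part.assignment[u] != part.assignment[v]

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(20, 0.2, seed=5)
        g = nx.relabel_nodes(g, {n: f"sp{n:02d}" for n in g})
        a = leiden_cpm(g, gamma=0.4, seed=123)
        b = leiden_cpm(g, gamma=0.4, seed=123)
        assert a.assignment == b.assignment and a.quality == b.quality

    def test_quality_matches_recomputation(self):
        g = nx.gnp_random_graph(15, 0.3, seed=9)
        part = leiden_cpm(g, gamma=0.6)
        assert part.quality == cpm_quality(g, part.assignment, part.gamma)

    def test_matches_exhaustive_optimum_small_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1_000_000)))
            gamma = float(rng.uniform(0.3, 1.0))
            part = leiden_cpm(g, gamma=gamma)
            best = exhaustive_cpm_optimum(list(g.nodes()), list(g.edges()), gamma)
            assert part.quality == pytest.approx(best, abs=1e-9)


class TestHubScores:
    def test_star_closed_form(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        scores = hub_scores(g)
        assert scores[0] == pytest.approx(1.0, abs=1e-9)
        for leaf in range(1, 5):
            assert scores[leaf] == pytest.approx(0.5, abs=1e-9)

    def test_path_closed_form(self):
        g = nx.path_graph(3)
        scores = hub_scores(g)
        assert scores[1] == pytest.approx(1.0, abs=1e-9)
        assert scores[0] == pytest.approx(1 / math.sqrt(2), abs=1e-9)
        assert scores[2] == pytest.approx(1 / math.sqrt(2), abs=1e-9)

    def test_regular_graph_uniform(self):
        g = nx.cycle_graph(6)
        scores = hub_scores(g)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in scores.values())

    def test_relabeling_invariance_and_range(self):
        g = nx.gnp_random_graph(12, 0.3, seed=2)
        scores = hub_scores(g)
        mapping = {n: f"node{n:02d}" for n in g}
        relabeled = hub_scores(nx.relabel_nodes(g, mapping))
        for n in g:
            assert relabeled[mapping[n]] == pytest.approx(scores[n], abs=1e-9)
        assert all(0 <= v <= 1 for v in scores.values())
        assert max(scores.values()) == pytest.approx(1.0)

    def test_disconnected_graph_all_nodes_scored(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")])
        scores = hub_scores(g)
        assert set(scores) == {"a", "b", "c", "x", "y"}
        assert max(scores.values()) == pytest.approx(1.0)
        # the denser component dominates
        assert scores["a"] > scores["x"]


class TestBetweenness:
    def test_path_single_intermediate(self):
        scores = betweenness(nx.path_graph(3))
        assert scores == {0: 0.0, 1: 1.0, 2: 0.0}

    def test_star_center(self):
        scores = betweenness(nx.star_graph(4))
        assert scores[0] == pytest.approx(6.0)  # C(4,2) leaf pairs

    def test_complete_graph_zero(self):
        scores = betweenness(nx.complete_graph(5))
        assert all(v == 0.0 for v in scores.values())

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(8):
            n = int(rng.integers(5, 25))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1_000_000)))
            expected = naive_betweenness(list(g.nodes()), list(g.edges()))
            actual = betweenness(g)
            for node in g:
                assert actual[node] == pytest.approx(expected[node], abs=1e-9)


class TestTopK:
    def test_descending_selection(self):
        assert top_k({"a": 3, "b": 2, "c": 1}, k=2) == ["a", "b"]

    def test_lexicographic_tie_break(self):
        assert top_k({"b": 1.0, "a": 1.0}, k=1) == ["a"]

    def test_k_exceeding_size_returns_all(self):
        assert top_k({"a": 1, "b": 2}, k=5) == ["b", "a"]

    def test_report_consistency(self):
        g = nx.star_graph(6)
        report = centrality_report(g, k=3)
        assert report.top_hub[0] == 0
        assert report.top_betweenness[0] == 0
        assert len(report.top_hub) == 3
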