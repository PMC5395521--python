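import networkx as nx
import numpy as np
import pytest

from simboost import AffinityMatrix, SimilarityMatrix
from simboost.graph_features import (build_bipartite_graph,
                                     build_similarity_graph, knn_summary,
                                     node_centralities,
                                     pair_network_averages)

from oracles import (betweenness_oracle, closeness_oracle, eigenvector_oracle,
                     pagerank_oracle)


def _sim(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"n{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(values, ids)


class TestBuildSimilarityGraph:
    def test_no_edges_below_threshold(self):
        s = _sim(np.eye(3))
        g = build_similarity_graph(s, 0.5)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 3

    def test_complete_graph_above_threshold(self):
        v = np.full((3, 3), 0.9)
        np.fill_diagonal(v, 1.0)
        g = build_similarity_graph(_sim(v), 0.5)
        assert g.number_of_edges() == 3

    def test_equality_with_threshold_is_not_an_edge(self):
        v = np.array([[1.0, 0.5], [0.5, 1.0]])
        g = build_similarity_graph(_sim(v), 0.5)
        assert g.number_of_edges() == 0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 10)
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            s = _sim(v)
            lo, hi = sorted(rng.random(2) * 0.99)
            e_lo = set(map(frozenset, build_similarity_graph(s, lo).edges))
            e_hi = set(map(frozenset, build_similarity_graph(s, hi).edges))
            assert e_hi <= e_lo


class TestBipartiteGraph:
    def test_edges_match_observed_mask_and_no_within_part_edges(self, toy_affinity):
        g = build_bipartite_graph(toy_affinity)
        assert g.number_of_edges() == int(toy_affinity.observed.sum())
        for u, v in g.edges:
            assert {u[0], v[0]} == {"drug", "target"}
        e = g.get_edge_data(("drug", "dA"), ("target", "t2"))
        assert e["weight"] == 2.0


class TestCentralities:
    def test_path_graph_betweenness(self):
        v = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        scores = node_centralities(build_similarity_graph(_sim(v, ["a", "b", "c"]), 0.5))
        assert scores["b"]["bt"] == pytest.approx(1.0)
        assert scores["a"]["bt"] == scores["c"]["bt"] == 0.0

    def test_complete_graph_pagerank_uniform(self):
        v = np.full((4, 4), 0.9)
        np.fill_diagonal(v, 1.0)
        scores = node_centralities(build_similarity_graph(_sim(v), 0.5))
        for s in scores.values():
            assert s["pr"] == pytest.approx(0.25, abs=1e-6)

    def test_star_graph_hub_dominates_eigenvector(self):
        v = np.eye(4)
        v[0, 1:] = v[1:, 0] = 0.9
        scores = node_centralities(build_similarity_graph(_sim(v), 0.5))
        hub = scores["n0"]["ev"]
        assert all(hub > scores[f"n{i}"]["ev"] for i in (1, 2, 3))

    def test_pagerank_sums_to_one_and_ev_unit_norm(self):
        rng = np.random.default_rng(1)
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        scores = node_centralities(build_similarity_graph(_sim(v), 0.5))
        pr = sum(s["pr"] for s in scores.values())
        ev = np.array([s["ev"] for s in scores.values()])
        assert pr == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(ev) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_agreement_with_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        weights = rng.random((n, n))
        weights = (weights + weights.T) / 2
        mask = rng.random((n, n)) < 0.4
        mask = mask | mask.T
        np.fill_diagonal(mask, False)
        adj = np.where(mask, weights, 0.0)
        g = nx.Graph()
        ids = [f"n{i:02d}" for i in range(n)]
        g.add_nodes_from(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j] > 0:
                    g.add_edge(ids[i], ids[j], weight=adj[i, j])
        scores = node_centralities(g)
        got = {k: np.array([scores[i][k] for i in ids])
               for k in ("bt", "cl", "ev", "pr")}
        support = (adj > 0).astype(float)
        np.testing.assert_allclose(got["bt"], betweenness_oracle(support), atol=1e-6)
        np.testing.assert_allclose(got["cl"], closeness_oracle(support), atol=1e-6)
        np.testing.assert_allclose(got["ev"], eigenvector_oracle(adj), atol=1e-6)
        np.testing.assert_allclose(got["pr"], pagerank_oracle(adj), atol=1e-6)


class TestKnnSummary:
    def _setup(self):
        v = np.array([
            [1.0, 0.8, 0.2],
            [0.8, 1.0, 0.6],
            [0.2, 0.6, 1.0],
        ])
        s = _sim(v, ["a", "b", "c"])
        g = build_similarity_graph(s, 0.1)
        type1 = {"a": np.array([2.0]), "b": np.array([1.0]), "c": np.array([3.0])}
        return s, g, type1

    def test_weighted_and_unweighted_neighbour_means(self):
        s, g, type1 = self._setup()
        out = knn_summary(s, g, "a", 2, type1)
        assert out["num_nb"] == 2
        assert out["k_sim"].tolist() == [0.8, 0.2]
        assert out["k_ave_feat"][0] == pytest.approx(2.0)
        assert out["k_w_ave_feat"][0] == pytest.approx(0.8 * 1.0 + 0.2 * 3.0)

    def test_equal_similarities_make_weighted_equal_unweighted(self):
        v = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, 0.7], [0.7, 0.7, 1.0]])
        s = _sim(v, ["a", "b", "c"])
        g = build_similarity_graph(s, 0.5)
        type1 = {"a": np.array([5.0]), "b": np.array([1.0]), "c": np.array([3.0])}
        out = knn_summary(s, g, "a", 2, type1)
        np.testing.assert_allclose(out["k_ave_feat"], out["k_w_ave_feat"])

    def test_ties_broken_by_ascending_id(self):
        v = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, 0.7], [0.7, 0.7, 1.0]])
        s = _sim(v, ["a", "b", "c"])
        g = build_similarity_graph(s, 0.5)
        type1 = {"a": np.array([5.0]), "b": np.array([1.0]), "c": np.array([3.0])}
        out = knn_summary(s, g, "a", 1, type1)
        assert out["k_ave_feat"][0] == 1.0  # "b" before "c" at equal similarity

    def test_isolated_node_pads_and_sentinels(self):
        s = _sim(np.eye(3))
        g = build_similarity_graph(s, 0.5)
        type1 = {f"n{i}": np.array([1.0]) for i in range(3)}
        out = knn_summary(s, g, "n0", 4, type1)
        assert out["num_nb"] == 0
        assert out["k_sim"].tolist() == [0.0] * 4
        assert np.isnan(out["k_ave_feat"]).all()


class TestPairNetworkAverages:
    def _graphs(self, toy_affinity):
        # target graph: t1-t2-t3 path via 0.9 edges; drug graph: complete
        tv = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        dv = np.full((3, 3), 0.9)
        np.fill_diagonal(dv, 1.0)
        g_t = build_similarity_graph(_sim(tv, ["t1", "t2", "t3"]), 0.5)
        g_d = build_similarity_graph(_sim(dv, ["dA", "dB", "dC"]), 0.5)
        return g_d, g_t

    def test_single_observed_neighbour_mean(self, toy_affinity):
        g_d, g_t = self._graphs(toy_affinity)
        # target t2's neighbours are t1 and t3; drug dB observes t1(4) and t3(6)
        d_t, _ = pair_network_averages(toy_affinity, g_d, g_t, "dB", "t2")
        assert d_t == pytest.approx(5.0)
        # drug dA observes t1=1 and t2=2; neighbours of t1 = {t2} -> mean 2
        d_t, _ = pair_network_averages(toy_affinity, g_d, g_t, "dA", "t1")
        assert d_t == pytest.approx(2.0)

    def test_no_qualifying_observation_gives_nan(self):
        vals = np.array([[1.0, np.nan], [np.nan, 2.0]])
        m = AffinityMatrix(vals, ~np.isnan(vals), ["d1", "d2"], ["t1", "t2"])
        g_d = build_similarity_graph(_sim(np.eye(2), ["d1", "d2"]), 0.5)
        g_t = build_similarity_graph(_sim(np.eye(2), ["t1", "t2"]), 0.5)
        d_t, t_d = pair_network_averages(m, g_d, g_t, "d1", "t1")
        assert np.isnan(d_t) and np.isnan(t_d)
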