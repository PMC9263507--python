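import numpy as np
import pytest

from richconn.core import ConnectivityMatrix
from richconn.metrics import (
    GlobalMetrics,
    NullModelConfig,
    global_metrics,
    nodal_metrics,
    rewire_preserving_degree,
    shortest_distances,
)

from conftest import complete_matrix, matrix_from_edges
from oracles import brute_betweenness, brute_distances, random_weighted_graph


class TestShortestDistances:
    def test_indirect_route_beats_weak_direct_edge(self, triangle):
        # 1/0.5 + 1/0.5 = 4 via the middle node vs 10 direct
        D = shortest_distances(triangle)
        assert D[0, 2] == pytest.approx(4.0)

    def test_complete_graph_all_unit(self):
        D = shortest_distances(complete_matrix(5))
        off = ~np.eye(5, dtype=bool)
        assert np.all(D[off] == 1.0)

    def test_disconnected_pairs_infinite(self):
        m = matrix_from_edges(4, [(0, 1, 1.0), (2, 3, 1.0)])
        D = shortest_distances(m)
        assert np.isinf(D[0, 2]) and np.isinf(D[1, 3])
        assert D[0, 1] == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            w = random_weighted_graph(rng, n=6)
            m = ConnectivityMatrix.from_array(w)
            np.testing.assert_allclose(
                shortest_distances(m), brute_distances(m.weights), atol=1e-9
            )


class TestNodalMetrics:
    def test_star_betweenness(self, star5):
        nm = nodal_metrics(star5)
        assert nm.bc[0] == pytest.approx(6.0)  # (n-1)(n-2)/2 leaf pairs
        assert np.all(nm.bc[1:] == 0)

    def test_triangle_clustering_is_one(self):
        nm = nodal_metrics(complete_matrix(3), mode="binary")
        np.testing.assert_allclose(nm.ncc, 1.0)

    def test_path_nodal_efficiency(self, path3):
        nm = nodal_metrics(path3)
        assert nm.ne[0] == pytest.approx(0.75)  # (1/1 + 1/2) / 2
        assert nm.nlp[0] == pytest.approx(1.5)

    def test_degree_and_strength(self, star5):
        nm = nodal_metrics(star5)
        assert nm.dc[0] == 4 and nm.strength[0] == pytest.approx(4.0)
        assert np.all(nm.dc[1:] == 1)

    def test_too_small_for_clustering(self):
        with pytest.raises(ValueError):
            nodal_metrics(matrix_from_edges(2, [(0, 1, 1.0)]))

    def test_betweenness_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            w = random_weighted_graph(rng, n=6)
            m = ConnectivityMatrix.from_array(w)
            np.testing.assert_allclose(
                nodal_metrics(m).bc, brute_betweenness(m.weights), atol=1e-9
            )

    def test_efficiency_jensen_bound(self):
        # on connected graphs, mean(1/d) >= 1/mean(d) per node
        rng = np.random.default_rng(3)
        for _ in range(10):
            w = random_weighted_graph(rng, n=7, p_edge=0.8)
            m = ConnectivityMatrix.from_array(w)
            D = shortest_distances(m)
            if np.isinf(D).any():
                continue
            nm = nodal_metrics(m)
            assert np.all(nm.ne >= 1.0 / nm.nlp - 1e-12)

    def test_weight_scaling_invariances(self):
        rng = np.random.default_rng(5)
        w = random_weighted_graph(rng, n=7, p_edge=0.7)
        # keep weights < 1 after scaling so modes stay comparable
        m1 = ConnectivityMatrix.from_array(0.5 * w)
        m2 = ConnectivityMatrix.from_array(1.5 * (0.5 * w))
        a, b = nodal_metrics(m1), nodal_metrics(m2)
        np.testing.assert_allclose(b.bc, a.bc, atol=1e-9)
        np.testing.assert_array_equal(b.dc, a.dc)
        np.testing.assert_allclose(
            shortest_distances(m2), shortest_distances(m1) / 1.5, atol=1e-9
        )
        assert np.array_equal(np.argsort(a.ne), np.argsort(b.ne))


class TestGlobalMetrics:
    def test_complete_k4_closed_form(self):
        gm = global_metrics(complete_matrix(4))
        assert gm.eglob == pytest.approx(1.0)
        assert gm.cp == pytest.approx(1.0)
        assert gm.lp == pytest.approx(1.0)

    def test_path3_characteristic_path_length(self, path3):
        gm = global_metrics(path3)
        assert gm.lp == pytest.approx(4.0 / 3.0)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            global_metrics(ConnectivityMatrix.from_array(np.zeros((3, 3))))

    def test_random_graph_sigma_near_one(self):
        rng = np.random.default_rng(21)
        n = 30
        w = (rng.random((n, n)) < 0.3).astype(float)
        w = np.triu(w, 1)
        m = ConnectivityMatrix.from_array(w + w.T)
        gm = global_metrics(m, nulls=NullModelConfig(n_null=20, seed=2))
        assert gm.sigma == pytest.approx(1.0, abs=0.15)

    def test_ring_lattice_more_smallworld_than_random(self):
        n, k = 50, 4
        w = np.zeros((n, n))
        for i in range(n):
            for d in range(1, k // 2 + 1):
                j = (i + d) % n
                w[i, j] = w[j, i] = 1.0
        ring = ConnectivityMatrix.from_array(w)
        nulls = NullModelConfig(n_null=20, seed=4)
        sigma_ring = global_metrics(ring, nulls=nulls).sigma
        rand = rewire_preserving_degree(ring, NullModelConfig(seed=99))
        sigma_rand = global_metrics(rand, nulls=nulls).sigma
        assert sigma_ring > sigma_rand


class TestRewiring:
    def _demo_matrix(self):
        rng = np.random.default_rng(13)
        w = random_weighted_graph(rng, n=20, p_edge=0.25)
        return ConnectivityMatrix.from_array(w)

    def test_degree_sequence_preserved(self):
        m = self._demo_matrix()
        null = rewire_preserving_degree(m, NullModelConfig(seed=1))
        np.testing.assert_array_equal(null.degrees(), m.degrees())

    def test_weight_multiset_carried(self):
        m = self._demo_matrix()
        null = rewire_preserving_degree(m, NullModelConfig(seed=1))
        np.testing.assert_allclose(
            np.sort(null.weights[null.weights > 0]),
            np.sort(m.weights[m.weights > 0]),
        )

    def test_same_seed_identical(self):
        m = self._demo_matrix()
        a = rewire_preserving_degree(m, NullModelConfig(seed=5))
        b = rewire_preserving_degree(m, NullModelConfig(seed=5))
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_triangle_has_no_valid_swap(self):
        tri = complete_matrix(3)
        null = rewire_preserving_degree(tri, NullModelConfig(seed=0))
        np.testing.assert_array_equal(null.weights, tri.weights)

    def test_topology_actually_changes(self):
        m = self._demo_matrix()
        null = rewire_preserving_degree(m, NullModelConfig(seed=8))
        assert not np.array_equal(null.weights > 0, m.weights > 0)
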