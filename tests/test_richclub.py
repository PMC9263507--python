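import numpy as np
import pytest

from richconn.core import ConnectivityMatrix
from richconn.metrics import NullModelConfig
from richconn.richclub import (
    classify_edges,
    count_abnormal_per_node,
    hubs_from_profile,
    identify_hubs,
    normalized_rich_club,
    rich_club_coefficient,
    rich_club_curve,
)
from richconn.simulate import CohortConfig, DEFAULT_HUB_NODES, generate_cohort

from conftest import complete_matrix, matrix_from_edges


def planted_club_graph(rng, n_core=10, n_peri=30, p_core=0.9, p_peri=0.1):
    n = n_core + n_peri
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_core if (i < n_core and j < n_core) else p_peri
            if rng.random() < p:
                w[i, j] = w[j, i] = rng.uniform(0.3, 0.7)
    return ConnectivityMatrix.from_array(w)


class TestRichClubCoefficient:
    def test_clique_plus_pendant(self):
        # K4 on nodes 0-3 plus pendant node 4 attached to node 0
        edges = [(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)]
        edges.append((0, 4, 1.0))
        m = matrix_from_edges(5, edges)
        phi, phi_w = rich_club_coefficient(m, k=1)
        assert phi == pytest.approx(1.0)

    def test_complete_k5_all_defined_k(self):
        m = complete_matrix(5)
        for k in range(4):
            phi, phi_w = rich_club_coefficient(m, k)
            assert phi == pytest.approx(1.0)
            assert phi_w == pytest.approx(1.0)

    def test_star_club_of_one_flagged_undefined(self, star5):
        phi, phi_w = rich_club_coefficient(star5, k=1)
        assert np.isnan(phi) and np.isnan(phi_w)
        curve = rich_club_curve(star5, k_values=[0, 1])
        assert curve.defined[0] and not curve.defined[1]

    def test_phi_scale_invariant_phi_w_linear(self):
        rng = np.random.default_rng(2)
        m = planted_club_graph(rng, n_core=5, n_peri=10)
        for k in range(1, 5):
            p1, w1 = rich_club_coefficient(m, k)
            m2 = ConnectivityMatrix.from_array(3.0 * m.weights)
            p2, w2 = rich_club_coefficient(m2, k)
            if np.isnan(p1):
                assert np.isnan(p2)
            else:
                assert p2 == pytest.approx(p1)
                assert w2 == pytest.approx(3.0 * w1)


class TestNormalizedRichClub:
    def test_er_graph_near_unity(self):
        rng = np.random.default_rng(40)
        n = 40
        a = (rng.random((n, n)) < 0.25).astype(float) * rng.uniform(0.3, 0.7, (n, n))
        a = np.triu(a, 1)
        m = ConnectivityMatrix.from_array(a + a.T)
        curve = normalized_rich_club(m, NullModelConfig(n_null=20, seed=1))
        deg = m.degrees()
        lo, hi = np.quantile(deg, [0.25, 0.75])
        mid = (curve.k_values >= lo) & (curve.k_values <= hi) & np.isfinite(curve.phi_norm)
        assert np.abs(curve.phi_norm[mid] - 1).mean() < 0.1

    def test_planted_core_shows_rich_club(self):
        hits = 0
        for seed in range(10):
            m = planted_club_graph(np.random.default_rng(seed))
            curve = normalized_rich_club(m, NullModelConfig(n_null=10, seed=seed))
            deg = m.degrees()
            high = curve.k_values >= np.quantile(deg, 0.75)
            vals = curve.phi_norm[high & np.isfinite(curve.phi_norm)]
            if len(vals) and vals.max() > 1:
                hits += 1
        assert hits >= 9

    def test_same_seed_identical_curve(self):
        m = planted_club_graph(np.random.default_rng(3))
        c1 = normalized_rich_club(m, NullModelConfig(n_null=5, seed=9))
        c2 = normalized_rich_club(m, NullModelConfig(n_null=5, seed=9))
        np.testing.assert_array_equal(c1.phi_norm, c2.phi_norm)


class TestHubs:
    def test_sd_rule_worked_example(self):
        profile = np.array([10, 10, 10, 2, 2, 2, 2, 2], float)
        hubs = hubs_from_profile(profile, method="sd_rule")
        assert hubs.threshold == pytest.approx(5 + np.sqrt(15))
        assert set(hubs.hubs) == {0, 1, 2}

    def test_top_k_consistent_with_sd_rule(self):
        profile = np.array([10, 10, 10, 2, 2, 2, 2, 2], float)
        assert set(hubs_from_profile(profile, "top_k", k_top=3).hubs) == {0, 1, 2}

    def test_top_k_tie_breaks_to_lower_index(self):
        profile = np.array([5, 7, 5, 3], float)
        hubs = hubs_from_profile(profile, "top_k", k_top=2)
        assert hubs.hubs == (1, 0)

    def test_planted_hubs_recovered_from_cohort(self, default_cohort):
        subjects, truth = default_cohort
        hubs = identify_hubs(subjects, method="top_k", k_top=13)
        assert sorted(hubs.hubs) == sorted(truth["hub_nodes"])
        # ordering is by descending averaged degree
        degs = [hubs.mean_degrees[h] for h in hubs.hubs]
        assert degs == sorted(degs, reverse=True)

    def test_mixed_node_counts_rejected(self):
        a = complete_matrix(4)
        b = complete_matrix(5)
        with pytest.raises(ValueError):
            identify_hubs([a, b])


class TestEdgeClassification:
    def test_partition_by_hub_endpoints(self, default_cohort):
        subjects, truth = default_cohort
        m = subjects[0].matrix
        hubs = identify_hubs(subjects, k_top=13)
        table = classify_edges(m, hubs)
        assert len(table) == m.n_edges
        hub_set = set(hubs.hubs)
        for row in table.itertuples():
            n_hub = (row.i in hub_set) + (row.j in hub_set)
            assert row.edge_class == ("local", "feeder", "rich_club")[n_hub]

    def test_empty_hub_set_all_local(self, triangle):
        from richconn.richclub import HubSet

        empty = HubSet(method="top_k", hubs=(), mean_degrees=np.zeros(3), threshold=0.0)
        table = classify_edges(triangle, empty)
        assert (table["edge_class"] == "local").all()

    def test_classes_partition_edge_set(self, default_cohort):
        subjects, _ = default_cohort
        m = subjects[0].matrix
        hubs = identify_hubs(subjects, k_top=13)
        table = classify_edges(m, hubs)
        assert table["edge_class"].value_counts().sum() == m.n_edges


class TestAbnormalCounts:
    def test_incidence_counting(self):
        counts = count_abnormal_per_node([(1, 2, "increased"), (1, 3, "decreased")], 5)
        row = counts.set_index("node")
        assert row.loc[1, "n_total"] == 2
        assert row.loc[1, "n_increased"] == 1 and row.loc[1, "n_decreased"] == 1

    def test_empty_input_all_zero(self):
        counts = count_abnormal_per_node([], 4)
        assert counts["n_total"].sum() == 0

    def test_handshake_identity(self):
        edges = [(7, i, "increased") for i in range(5)]
        counts = count_abnormal_per_node(edges, 10)
        assert counts.set_index("node").loc[7, "n_total"] == 5
        assert counts["n_total"].sum() == 10
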