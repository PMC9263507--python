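import numpy as np
import pytest
from scipy import stats as sps

from richconn.core import DOMAIN_NAMES
from richconn.simulate import CohortConfig, generate_cohort
from richconn.stats import (
    DegenerateResultWarning,
    adjust_covariates,
    bonferroni,
    classify_ani,
    compare_value_table,
    edge_comparison,
    nodal_comparison,
    partial_correlation,
    two_sample_t,
)
from richconn.core import select_group


class TestAdjustCovariates:
    def test_no_covariate_signal_centers_values(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 50, 30)
        sex = (rng.random(30) < 0.5).astype(float)
        values = np.full(30, 7.0)
        resid = adjust_covariates(values, age, sex)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_perfect_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(20, 50, 30)
        sex = (rng.random(30) < 0.5).astype(float)
        resid = adjust_covariates(2.0 * age, age, sex)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_collinear_covariate_named(self):
        age = np.linspace(20, 40, 10)
        with pytest.raises(np.linalg.LinAlgError, match="sex"):
            adjust_covariates(np.arange(10.0), age, 2 * age)

    def test_group_effect_survives_adjustment(self):
        # planted value = group_effect + 0.5*age + noise; adjusted t close to
        # the noise-only oracle t over simulations
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(100):
            n = 24
            age = rng.uniform(20, 50, 2 * n)
            sex = np.r_[np.ones(4), np.zeros(2 * n - 4)]
            rng.shuffle(sex)
            noise = rng.normal(0, 1, 2 * n)
            group = np.r_[np.ones(n), np.zeros(n)]
            values = 0.8 * group + 0.5 * age + noise
            resid = adjust_covariates(values, age, sex)
            t_adj, _ = two_sample_t(resid[:n], resid[n:])
            oracle = 0.8 * group + noise
            t_oracle, _ = two_sample_t(oracle[:n], oracle[n:])
            diffs.append(t_adj - t_oracle)
        assert abs(np.mean(diffs)) < 0.2


class TestTwoSampleT:
    def test_worked_example(self):
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-3)
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swap_flips_sign_preserves_p(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        with pytest.warns(DegenerateResultWarning):
            t, p = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            _, p = two_sample_t(rng.normal(size=24), rng.normal(size=24))
            rejections += p < 0.05
        assert 0.035 <= rejections / n_sims <= 0.065


class TestBonferroni:
    def test_arithmetic(self):
        assert bonferroni(0.01, 90) == pytest.approx(0.9)
        assert bonferroni(0.5, 90) == 1.0

    def test_idempotent_ordering_free_and_dominates(self):
        ps = [0.001, 0.02, 0.7]
        out = [bonferroni(p, 3) for p in ps]
        assert all(b >= p for p, b in zip(ps, out))
        assert [bonferroni(p, 3) for p in reversed(ps)] == list(reversed(out))


class TestNodalComparison:
    @pytest.fixture(scope="class")
    def null_cohorts(self):
        cfg = CohortConfig(seed=11, effect_edges=(), age_slope=0.0, n_ani=8, n_nonhand=8, n_hc=16)
        subjects, _ = generate_cohort(cfg)
        return select_group(subjects, "HIV"), select_group(subjects, "HC")

    def test_constant_metric_is_degenerate_not_significant(self, null_cohorts):
        a, b = null_cohorts
        table = nodal_comparison(a, b, metrics=("dc",))
        # shared topology -> binary degree has no variance -> flagged p = 1
        assert (table["p"] == 1.0).all()
        assert not table["significant_raw"].any()

    def test_bonferroni_family_is_node_count(self, null_cohorts):
        a, b = null_cohorts
        table = nodal_comparison(a, b, metrics=("ne",))
        np.testing.assert_allclose(
            table["p_bonf"], np.minimum(1.0, table["p"] * 90), atol=1e-12
        )

    def test_direction_matches_sign(self, null_cohorts):
        a, b = null_cohorts
        table = nodal_comparison(a, b, metrics=("ne", "strength"))
        inc = table[table["t"] > 0]
        assert (inc["direction"] == "increased").all()

    def test_planted_efficiency_deficit_detected(self):
        # a 1.5-pooled-SD nodal-efficiency deficit at one node, n=24 vs 24
        rng = np.random.default_rng(12)
        detected = 0
        n_seeds = 50
        for _ in range(n_seeds):
            n = 24
            values_a = rng.normal(10, 1, n)
            values_b = rng.normal(10, 1, n)
            sd = np.sqrt((values_a.var(ddof=1) + values_b.var(ddof=1)) / 2)
            values_a = values_a - 1.5 * sd
            age = rng.uniform(25, 45, 2 * n)
            sex = np.r_[np.ones(2), np.zeros(2 * n - 2)]
            rng.shuffle(sex)
            resid = adjust_covariates(np.r_[values_a, values_b], age, sex)
            t, p = two_sample_t(resid[:n], resid[n:])
            detected += (p < 0.05) and (t < 0)
        assert detected / n_seeds >= 0.95


class TestEdgeComparison:
    def test_planted_edge_shift_detected(self):
        cfg = CohortConfig(seed=13)
        subjects, truth = generate_cohort(cfg)
        hiv, hc = select_group(subjects, "HIV"), select_group(subjects, "HC")
        hiv_edges = [
            (e["i"], e["j"], e["delta"]) for e in truth["effect_edges"] if e["group"] == "HIV"
        ]
        table = edge_comparison(hiv, hc, [(i, j) for i, j, _ in hiv_edges])
        for (_, _, delta), row in zip(hiv_edges, table.itertuples()):
            assert np.sign(row.t) == np.sign(delta)
        assert table["significant_raw"].sum() >= 4  # d = 1 at n = 48/48

    def test_all_zero_edge_skipped(self, small_cohort):
        subjects, _ = small_cohort
        hiv, hc = select_group(subjects, "HIV"), select_group(subjects, "HC")
        # find a pair absent in every subject
        union = np.zeros_like(hiv[0].matrix.weights, dtype=bool)
        for s in hiv + hc:
            union |= s.matrix.weights > 0
        zi, zj = np.argwhere(~np.triu(union, 1) & ~np.tri(len(union), dtype=bool))[0]
        table = edge_comparison(hiv, hc, [(int(zi), int(zj))])
        assert len(table) == 0


class TestClassifyAni:
    MEANS = {d: 50.0 for d in DOMAIN_NAMES}
    SDS = {d: 10.0 for d in DOMAIN_NAMES}

    def make_scores(self, **overrides):
        scores = {d: 50.0 for d in DOMAIN_NAMES}
        scores.update(overrides)
        return scores

    def test_two_low_domains_is_ani_pattern(self):
        scores = self.make_scores(
            verbal_fluency=50 - 12.0, fine_motor_skills=50 - 12.0
        )
        assert classify_ani(scores, self.MEANS, self.SDS) == "ANI_pattern"

    def test_single_very_low_domain_is_normal(self):
        scores = self.make_scores(verbal_fluency=50 - 30.0)
        assert classify_ani(scores, self.MEANS, self.SDS) == "normal"

    def test_boundary_exactly_one_sd_counts(self):
        scores = {d: 40.0 for d in DOMAIN_NAMES}  # all exactly mean - 1 SD
        assert classify_ani(scores, self.MEANS, self.SDS) == "ANI_pattern"

    def test_missing_domain_rejected(self):
        scores = self.make_scores()
        del scores["verbal_fluency"]
        with pytest.raises(KeyError):
            classify_ani(scores, self.MEANS, self.SDS)


class TestPartialCorrelation:
    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        covs = rng.normal(size=(40, 2))
        r, p = partial_correlation(x, x, covs)
        assert r == pytest.approx(1.0)

    def test_empty_covariates_equals_pearson(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_recovers_true_partial_r(self):
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(30):
            n = 1000
            c = rng.normal(size=(n, 2))
            ex = rng.normal(size=n)
            ey = 0.5 * ex + np.sqrt(0.75) * rng.normal(size=n)  # true partial r = .5
            x = ex + c @ [1.0, -0.5]
            y = ey + c @ [0.3, 0.8]
            r, _ = partial_correlation(x, y, c)
            estimates.append(r)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.06)

    def test_shared_covariate_removed(self):
        rng = np.random.default_rng(8)
        n = 500
        age = rng.uniform(20, 60, n)
        x = 2.0 * age + rng.normal(scale=1e-6, size=n)
        y = rng.normal(size=n)
        r, _ = partial_correlation(x, y, age[:, None])
        assert abs(r) < 0.1

    def test_zero_variance_flagged(self):
        age = np.linspace(20, 40, 20)
        with pytest.warns(DegenerateResultWarning):
            r, p = partial_correlation(2 * age, np.arange(20.0), age[:, None])
        assert np.isnan(r)
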