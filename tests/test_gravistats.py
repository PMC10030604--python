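"""Repeated-measures ANOVA, Tukey, Friedman, ROUT, densities, subgroups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gravimea import gravistats as gs

from _oracles import FIXTURE_6x4, FIXTURE_6x4_EXPECTED, rm_anova_oracle


def correlated_lognormal(rng, n=20, k=4, subject_sd=0.5, noise_sd=0.2):
    """Null data resembling unit rates: shared subject level + noise, lognormal."""
    log_rate = rng.normal(np.log(3), subject_sd, (n, 1)) + rng.normal(0, noise_sd, (n, k))
    return np.exp(log_rate)


class TestRMAnovaGG:
    def test_constant_rows_give_zero_F(self):
        x = np.tile(np.array([[1.0], [2.0], [5.0], [3.0]]), (1, 4))
        r = gs.rm_anova_gg(x)
        assert r.F == 0.0
        assert r.p_gg == 1.0

    def test_two_conditions_epsilon_one_and_F_equals_t_squared(self, rng):
        x = rng.normal(0, 1, (12, 2)) + rng.normal(0, 1, (12, 1))
        r = gs.rm_anova_gg(x)
        t = stats.ttest_rel(x[:, 0], x[:, 1])
        assert r.epsilon_gg == 1.0
        assert r.F == pytest.approx(t.statistic**2)
        assert r.p_gg == pytest.approx(t.pvalue)

    def test_fixture_matches_step_by_step_oracle(self):
        r = gs.rm_anova_gg(FIXTURE_6x4)
        oracle = rm_anova_oracle(FIXTURE_6x4)
        assert r.F == pytest.approx(oracle["F"], abs=1e-6)
        assert r.epsilon_gg == pytest.approx(oracle["eps"], abs=1e-6)
        assert r.p_gg == pytest.approx(oracle["p"], rel=1e-6)
        # and against the frozen constants
        assert r.F == pytest.approx(FIXTURE_6x4_EXPECTED["F"], abs=1e-6)
        assert r.epsilon_gg == pytest.approx(FIXTURE_6x4_EXPECTED["eps"], abs=1e-6)
        assert r.p_gg == pytest.approx(FIXTURE_6x4_EXPECTED["p"], rel=1e-4)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = correlated_lognormal(rng, n=10, k=5)
        r = gs.rm_anova_gg(np.log10(x))
        df = (
            pd.DataFrame(np.log10(x))
            .reset_index()
            .melt("index", var_name="cond", value_name="y")
        )
        ref = pg.rm_anova(data=df, dv="y", within="cond", subject="index", correction=True)
        assert r.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert r.epsilon_gg == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-9)
        assert r.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-9)

    def test_epsilon_bounds(self, rng):
        for k in (2, 3, 5):
            x = correlated_lognormal(rng, n=8, k=k, noise_sd=1.0)
            r = gs.rm_anova_gg(np.log10(x))
            assert 1.0 / (k - 1) - 1e-12 <= r.epsilon_gg <= 1.0 + 1e-12

    def test_incomplete_design_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            gs.rm_anova_gg(x)
        with pytest.raises(ValueError):
            gs.rm_anova_gg(np.ones((5, 1)))


class TestTukeyPairwise:
    def test_identical_means_give_p_one(self):
        x = np.tile(np.array([[1.0], [2.0], [4.0]]), (1, 3))
        r = gs.rm_anova_gg(x)
        for c in gs.tukey_pairwise(x, r):
            assert c.q == 0.0
            assert c.p_adj == 1.0

    def test_two_conditions_equal_paired_p(self, rng):
        x = rng.normal(0, 1, (15, 2)) + rng.normal(0, 1, (15, 1))
        r = gs.rm_anova_gg(x)
        (c,) = gs.tukey_pairwise(x, r)
        assert c.p_adj == pytest.approx(stats.ttest_rel(x[:, 0], x[:, 1]).pvalue, rel=1e-9)

    def test_fixture_q_values_match_oracle(self):
        r = gs.rm_anova_gg(FIXTURE_6x4)
        comps = gs.tukey_pairwise(FIXTURE_6x4, r)
        oracle = rm_anova_oracle(FIXTURE_6x4)["tukey"]
        got = {(c.a, c.b): c.q for c in comps}
        for (i, j), (q, _) in oracle.items():
            assert got[(f"cond{i}", f"cond{j}")] == pytest.approx(q, abs=1e-6)
        assert got[("cond0", "cond1")] == pytest.approx(FIXTURE_6x4_EXPECTED["q_01"], abs=1e-6)
        assert got[("cond0", "cond2")] == pytest.approx(FIXTURE_6x4_EXPECTED["q_02"], abs=1e-6)
        assert got[("cond0", "cond3")] == pytest.approx(FIXTURE_6x4_EXPECTED["q_03"], abs=1e-6)

    def test_antisymmetric_differences(self):
        r = gs.rm_anova_gg(FIXTURE_6x4)
        comps = {(c.a, c.b): c.mean_diff for c in gs.tukey_pairwise(FIXTURE_6x4, r)}
        means = FIXTURE_6x4.mean(axis=0)
        for (a, b), d in comps.items():
            i, j = int(a[-1]), int(b[-1])
            assert d == pytest.approx(means[i] - means[j])


class TestFriedman:
    def test_perfect_concordance_is_maximal(self):
        x = np.tile(np.array([1.0, 2.0, 3.0]), (10, 1)) + np.arange(10)[:, None]
        stat, p = gs.friedman_test(x)
        assert stat == pytest.approx(20.0)  # n (k - 1)

    def test_constant_rows_give_zero(self):
        stat, p = gs.friedman_test(np.ones((6, 4)))
        assert stat == 0.0
        assert p == 1.0

    def test_textbook_example_matches_scipy(self):
        x = np.array(
            [[7.0, 9.0, 8.0], [6.0, 5.0, 7.0], [9.0, 7.0, 6.0], [8.0, 5.0, 6.0]]
        )
        stat, p = gs.friedman_test(x)
        ref = stats.friedmanchisquare(*x.T)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_matches_scipy_with_ties(self, rng):
        x = np.round(correlated_lognormal(rng, n=12, k=4), 1)  # rounding makes ties
        stat, p = gs.friedman_test(x)
        ref = stats.friedmanchisquare(*x.T)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_invariance_under_monotone_transform(self, rng):
        x = correlated_lognormal(rng, n=10, k=4)
        s1 = gs.friedman_test(x)
        s2 = gs.friedman_test(np.log(x))
        s3 = gs.friedman_test(x**3)
        assert s1 == pytest.approx(s2)
        assert s1 == pytest.approx(s3)


class TestRoutOutliers:
    def test_gross_outlier_flagged(self):
        mask = gs.rout_outliers(np.array([0.0, 0.0, 0.0, 0.0, 0.0, 100.0]))
        assert mask.tolist() == [False] * 5 + [True]

    def test_identical_values_no_outliers(self):
        assert not gs.rout_outliers(np.full(10, 3.3)).any()

    def test_too_few_points_no_detection(self):
        assert not gs.rout_outliers(np.array([1.0, 2.0, 100.0])).any()

    def test_clean_gaussian_rarely_flagged(self, rng):
        flagged = 0
        for _ in range(300):
            mask = gs.rout_outliers(rng.normal(0, 1, 20), Q=0.01)
            flagged += mask.any()
        assert flagged / 300 <= 0.05

    def test_outlier_among_gaussian_noise(self, rng):
        x = rng.normal(0, 1, 30)
        x[7] = 25.0
        assert gs.rout_outliers(x)[7]


class TestDensityProfile:
    def test_normalized_on_grid(self, rng):
        prof = gs.density_profile(rng.lognormal(1.0, 0.5, 200))
        assert np.trapezoid(prof.density, prof.grid) == pytest.approx(1.0, abs=1e-3)
        assert np.all(prof.density >= 0)

    def test_tight_cluster_peak_location(self, rng):
        prof = gs.density_profile(3.0 + rng.normal(0, 0.2, 300))
        assert abs(prof.peak() - 3.0) <= 0.5

    def test_bimodal_clusters_resolved(self, rng):
        rates = np.r_[rng.normal(8.0, 1.0, 200), rng.normal(20.0, 1.5, 150)]
        prof = gs.density_profile(rates)
        maxima = prof.local_maxima()
        assert np.any(np.abs(maxima - 8.0) < 1.5)
        assert np.any(np.abs(maxima - 20.0) < 2.0)

    def test_degenerate_sample_uses_fallback_bandwidth(self):
        prof = gs.density_profile(np.full(10, 5.0))
        assert prof.bandwidth == pytest.approx(0.25)
        assert abs(prof.peak() - 5.0) < 0.2

    def test_too_few_rates_rejected(self):
        with pytest.raises(ValueError):
            gs.density_profile([3.0])


class TestSubgroupDeltas:
    def make_table(self, rates_ref, rates_tgt):
        return pd.DataFrame({"base": rates_ref, "micro": rates_tgt})

    def test_selects_extremes_and_middle(self):
        ref = np.arange(1.0, 31.0)  # unit ids 0..29 with increasing rates
        tgt = ref * 1.2
        groups = gs.subgroup_deltas(self.make_table(ref, tgt), "base", "micro", k=10)
        assert list(groups["low"].index) == list(range(10))
        assert list(groups["high"].index) == list(range(20, 30))
        assert list(groups["mid"].index) == list(range(10, 20))
        assert (groups["low"]["sign"] == 1).all()

    def test_k1_on_three_units(self):
        g = gs.subgroup_deltas(self.make_table([3.0, 1.0, 2.0], [1.0, 2.0, 3.0]), "base", "micro", k=1)
        assert list(g["low"].index) == [1]
        assert list(g["mid"].index) == [2]
        assert list(g["high"].index) == [0]

    def test_ties_broken_by_unit_id(self):
        ref = np.ones(6)
        tbl = self.make_table(ref, ref * 2)
        g = gs.subgroup_deltas(tbl, "base", "micro", k=2)
        assert list(g["low"].index) == [0, 1]
        assert list(g["high"].index) == [4, 5]

    def test_insufficient_units_rejected(self):
        with pytest.raises(ValueError):
            gs.subgroup_deltas(self.make_table([1.0, 2.0], [1.0, 2.0]), "base", "micro", k=1)
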