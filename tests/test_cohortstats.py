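"""Statistics layer: against exact enumeration, hand computation and
closed-form oracles wherever one exists."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar

from stromascope.cohortstats import (
    bonferroni,
    compare_groups,
    correlate,
    cox_fit,
    crosstab,
    crosstab_from_counts,
    delong_compare,
    dichotomize,
    km_logrank,
    ph_check,
    univariable_cox,
    univariable_screen,
)
from stromascope.errors import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        res = compare_groups(x, x.copy())
        assert res.statistic_name == "mannwhitney_u"
        assert res.p_raw == pytest.approx(1.0)

    def test_small_sample_u_equals_exhaustive_enumeration(self):
        """Exact two-sided MW p for n=4 vs 4 equals permutation enumeration."""
        x = np.array([1.3, 2.9, 0.7, 4.1])
        y = np.array([2.0, 5.5, 6.2, 3.3])
        res = compare_groups(x, y)
        pooled = np.r_[x, y]
        u_obs = stats.mannwhitneyu(x, y).statistic
        n1 = len(x)
        center = n1 * len(y) / 2
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            xa = pooled[list(idx)]
            ya = np.delete(pooled, list(idx))
            u = stats.mannwhitneyu(xa, ya).statistic
            total += 1
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                count += 1
        assert res.p_raw == pytest.approx(count / total)

    def test_normal_data_uses_t_test(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(0, 1, 80), rng.normal(0.1, 1, 80))
        assert res.statistic_name == "t"

    def test_skewed_data_uses_rank_test(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.exponential(1, 80), rng.exponential(1, 80))
        assert res.statistic_name == "mannwhitney_u"

    def test_rejection_rate_matches_monte_carlo_oracle(self):
        """Power of the dispatcher on shifted exponentials tracks a direct
        Mann-Whitney Monte-Carlo oracle within 5 points."""
        rng = np.random.default_rng(7)
        shift, n, reps = 0.25, 200, 500
        ours = oracle = 0
        for _ in range(reps):
            x = rng.exponential(1, n)
            y = rng.exponential(1, n) + shift
            ours += compare_groups(x, y).p_raw < 0.05
            oracle += stats.mannwhitneyu(x, y, alternative="two-sided").pvalue < 0.05
        assert abs(ours - oracle) / reps <= 0.05

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelate:
    def test_linear_pearson_one(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x).statistic == pytest.approx(1.0)

    def test_monotone_transform_spearman_one_pearson_below(self):
        x = np.linspace(0.1, 3, 30)
        y = np.exp(x)
        assert correlate(x, y, "spearman").statistic == pytest.approx(1.0)
        assert correlate(x, y, "pearson").statistic < 1.0

    def test_generator_correlation_recovered(self):
        from stromascope.synthcore import CohortSpec, generate_cohort
        df = generate_cohort(CohortSpec(n_patients=1000, seed=12))
        res = correlate(df["mri_pos_FAP_fraction"], df["mri_pos_CD8_fraction"],
                        "spearman")
        assert 0.34 <= res.statistic <= 0.54

    def test_constant_vector_missing(self):
        with pytest.warns(UserWarning):
            res = correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.statistic)


class TestDichotomize:
    def test_median_rule(self):
        labels, cutoff = dichotomize([1.0, 2, 3, 4], "median")
        assert cutoff == 2.5
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])

    def test_fixed_cutoff_is_strict(self):
        labels, _ = dichotomize([0.1, 0.19, 0.21, 0.5, 0.20], "fixed", cutoff=0.20)
        np.testing.assert_array_equal(labels, [0, 0, 1, 1, 0])

    def test_top_decile_counts(self):
        rng = np.random.default_rng(3)
        labels, _ = dichotomize(rng.random(280), "top_decile")
        assert labels.sum() == 28

    @given(st.integers(min_value=20, max_value=400))
    def test_top_decile_count_property(self, n):
        rng = np.random.default_rng(n)
        labels, _ = dichotomize(rng.random(n), "top_decile")
        assert labels.sum() == max(1, int(round(0.1 * n)))

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateInputError):
            dichotomize([2.0, 2.0, 2.0], "median")


def fisher_enumeration(table):
    """Oracle: two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    pmf = [stats.hypergeom.pmf(k, n, r1, c1) for k in range(max(0, c1 - r2),
                                                            min(r1, c1) + 1)]
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(sum(p for p in pmf if p <= p_obs * (1 + 1e-9)))


class TestCrossTab:
    def test_printed_association_table_reproduced(self):
        """Published PTEN x FAP counts: row percentages and Fisher p."""
        ct = crosstab_from_counts([[11, 36], [140, 115]], force_fisher=True)
        assert np.round(ct.row_percent[0]).tolist() == [23, 77]
        assert np.round(ct.row_percent[1]).tolist() == [55, 45]
        assert ct.test_used == "fisher_exact"
        assert ct.p < 0.001

    def test_symmetric_table_fisher_p_one(self):
        ct = crosstab_from_counts([[5, 5], [5, 5]], force_fisher=True)
        assert ct.p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_fisher_equals_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 50, size=(2, 2))
        t += 1  # avoid empty margins
        ct = crosstab_from_counts(t, force_fisher=True)
        assert ct.p == pytest.approx(fisher_enumeration(t), rel=1e-6)

    def test_from_observations_matches_counts(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        ct = crosstab(a, b)
        assert ct.counts.sum() == 100
        assert np.allclose(ct.row_percent.sum(axis=1), 100.0)

    def test_multilevel_table_uses_chi2(self):
        rng = np.random.default_rng(2)
        g = rng.integers(1, 6, 300)
        b = rng.integers(0, 2, 300)
        assert crosstab(g, b).test_used == "chi2"


class TestBonferroni:
    def test_printed_cap_example(self):
        # a raw p of 0.02 across a 53-variable family is not significant
        assert bonferroni(0.02, 53) == 1.0

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_monotone_and_capped(self, p1, p2):
        lo, hi = sorted([p1, p2])
        assert bonferroni(lo, 53) <= bonferroni(hi, 53) <= 1.0


class TestKaplanMeier:
    def test_identical_groups_chi2_zero(self):
        t = np.array([3.0, 5, 7, 9, 11, 2, 8])
        e = np.array([1, 0, 1, 1, 0, 1, 1])
        fit, _ = km_logrank(np.r_[t, t], np.r_[e, e],
                            np.r_[np.zeros(7), np.ones(7)])
        assert fit.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_three_subject_product_limit_by_hand(self):
        """times 1,2,3 / events 1,1,0: S = 2/3 after t=1, 1/3 after t=2."""
        _, curves = km_logrank([1.0, 2.0, 3.0], [1, 1, 0],
                               ["a", "a", "a"])
        s = dict(zip(curves["time"], curves["survival"]))
        assert s[0.0] == 1.0
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert s[3.0] == pytest.approx(1 / 3)

    def test_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        _, curves = km_logrank(t, e, np.repeat("g", 50))
        surv = curves["survival"].to_numpy()
        assert surv[0] == 1.0
        assert (np.diff(surv) <= 1e-12).all()

    def test_no_censoring_reaches_empirical_survivor_fraction(self):
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        e = np.ones(8, int)
        _, curves = km_logrank(t, e, np.repeat("g", 8))
        assert curves["survival"].iloc[-1] == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            km_logrank([1.0, 2.0], [0, 0], ["a", "a"])


class TestCox:
    def test_toy_binary_matches_hand_maximized_likelihood(self):
        """4-subject toy: betahat equals the numerically maximized
        two-sample partial likelihood (independent closed-form oracle)."""
        time = [1.0, 3.0, 2.0, 4.0]
        event = [1, 0, 1, 0]
        x = [0.0, 0.0, 1.0, 1.0]

        def negloglik(b):
            # event at t=1 (x=0, risk {all}), event at t=2 (x=1, risk {3,2,4})
            return -(-np.log(2 + 2 * np.exp(b)) + b - np.log(1 + 2 * np.exp(b)))

        oracle = minimize_scalar(negloglik, bounds=(-5, 5), method="bounded").x
        fit = cox_fit(time, event, pd.DataFrame({"x": x}))
        # analytic optimum is -ln(2)/2; lifelines converges to ~1e-3
        assert oracle == pytest.approx(-math.log(2) / 2, abs=1e-6)
        assert fit.coefs.loc["x", "beta"] == pytest.approx(oracle, abs=2e-3)

    def test_fast_screen_matches_lifelines(self):
        rng = np.random.default_rng(9)
        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        c = rng.exponential(30, n)
        time, ev = np.minimum(t, c), (t <= c).astype(int)
        fast = univariable_cox(time, ev, x)
        ll = cox_fit(time, ev, pd.DataFrame({"x": x}))
        assert fast.extra["beta"] == pytest.approx(ll.coefs.loc["x", "beta"],
                                                   abs=1e-4)
        assert fast.p_raw == pytest.approx(ll.coefs.loc["x", "p"], abs=1e-3)

    def test_zero_variance_covariate_degenerate(self):
        with pytest.raises(DegenerateInputError):
            univariable_cox([1.0, 2, 3, 4], [1, 1, 1, 0], [2.0, 2, 2, 2])

    def test_screen_bonferroni_capping(self):
        rng = np.random.default_rng(11)
        n = 100
        df = pd.DataFrame({
            "time_months": rng.exponential(30, n),
            "event": rng.integers(0, 2, n),
            "v0": rng.standard_normal(n),
            "v1": rng.standard_normal(n),
        })
        out = univariable_screen(df, ["v0", "v1"], family_size=53)
        for r in out:
            if r.p_corrected is not None:
                assert r.p_corrected == min(1.0, r.p_raw * 53)


class TestSchoenfeld:
    def test_ph_consistent_data_rarely_rejects(self):
        from stromascope.synthcore import CohortSpec, generate_cohort
        rej = 0
        reps = 60
        for s in range(reps):
            df = generate_cohort(CohortSpec(
                n_patients=150, baseline_hazard=0.006, seed=3000 + s))
            fit = cox_fit(df["time_months"], df["event"],
                          df[["mri_pos_FAP_fraction"]])
            p = ph_check(fit)["mri_pos_FAP_fraction"]
            rej += p < 0.05
        assert rej / reps <= 0.15

    def test_crossing_hazards_detected(self):
        from stromascope.synthcore import CohortSpec, generate_cohort
        rej = 0
        reps = 30
        for s in range(reps):
            df = generate_cohort(CohortSpec(
                n_patients=300, baseline_hazard=0.02, censoring_rate=0.002,
                log_hazard_fap=math.log(4), log_hazard_sma=0.0,
                hazard_form="median",
                time_varying_fap_effect=True, seed=4000 + s))
            fit = cox_fit(df["time_months"], df["event"],
                          df[["mri_pos_FAP_fraction"]])
            rej += ph_check(fit)["mri_pos_FAP_fraction"] < 0.05
        assert rej / reps >= 0.5

    def test_unfitted_input_rejected(self):
        from stromascope.cohortstats import SurvivalFit
        with pytest.raises(ParameterError):
            ph_check(SurvivalFit(model="cox", converged=False))


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60)
        a = rng.standard_normal(60)
        res = delong_compare(y, a, a)
        assert res.effect == 0.0
        assert res.p_raw == 1.0

    def test_auc_equals_mannwhitney_identity(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        a = rng.standard_normal(200) + 0.8 * y
        res = delong_compare(y, a, rng.standard_normal(200))
        u = stats.mannwhitneyu(a[y == 1], a[y == 0]).statistic
        assert res.extra["auc_a"] == pytest.approx(
            u / ((y == 1).sum() * (y == 0).sum()))

    def test_one_class_outcome_rejected(self):
        with pytest.raises(InsufficientDataError):
            delong_compare(np.ones(20, int), np.random.rand(20),
                           np.random.rand(20))
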