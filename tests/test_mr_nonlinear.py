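"""Tests of doubly-ranked stratification and fractional-polynomial MR."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrdose import assoc, instruments as ins, linear, nonlinear
from mrdose.nonlinear import StratumEstimate
from mrdose.simulate import CausalCurve, SimConfig, simulate_cohort, true_curve


def _flat_strata(theta=0.4, se=0.05, S=10, lo=0.5, hi=3.5, rng=None):
    xbar = np.linspace(lo, hi, S)
    out = []
    for k in range(S):
        noise = 0.0 if rng is None else rng.normal(0, se)
        out.append(StratumEstimate(k + 1, 100, float(xbar[k]), theta + noise, se))
    return out


class TestDoublyRanked:
    def test_hand_enumerated_example(self):
        """n=9, S=3, instrument order 1..9, exposures (5,1,9 | 4,2,8 | 3,7,6)."""
        score = np.arange(1.0, 10.0)
        expo = np.array([5, 1, 9, 4, 2, 8, 3, 7, 6], float)
        a = nonlinear.doubly_ranked_strata(score, expo, 3)
        assert sorted(expo[a == 1]) == [1, 2, 3]
        assert sorted(expo[a == 2]) == [4, 5, 6]
        assert sorted(expo[a == 3]) == [7, 8, 9]

    def test_monotone_exposure_in_instrument(self):
        rng = np.random.default_rng(40)
        score = rng.standard_normal(100)
        expo = 2.0 * score  # strictly increasing in instrument
        a = nonlinear.doubly_ranked_strata(score, expo, 10)
        xbars = [expo[a == k].mean() for k in range(1, 11)]
        assert xbars == sorted(xbars)

    def test_exact_sizes_when_divisible(self):
        rng = np.random.default_rng(41)
        a = nonlinear.doubly_ranked_strata(
            rng.standard_normal(200), rng.standard_normal(200), 10
        )
        assert all((a == k).sum() == 20 for k in range(1, 11))

    def test_remainder_goes_to_lowest_strata(self):
        rng = np.random.default_rng(42)
        n, S = 103, 10
        a = nonlinear.doubly_ranked_strata(
            rng.standard_normal(n), rng.standard_normal(n), S
        )
        sizes = np.array([(a == k).sum() for k in range(1, S + 1)])
        assert sizes.sum() == n
        np.testing.assert_array_equal(sizes, [11, 11, 11] + [10] * 7)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            nonlinear.doubly_ranked_strata(np.arange(8.0), np.arange(8.0), 3)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance_of_assignment(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        score, expo = rng.standard_normal(n), rng.standard_normal(n)
        a = nonlinear.doubly_ranked_strata(score, expo, 6)
        perm = rng.permutation(n)
        a_perm = nonlinear.doubly_ranked_strata(score[perm], expo[perm], 6)
        np.testing.assert_array_equal(a[perm], a_perm)
        assert a.sum() == a_perm.sum()  # sum(n_k * k) preserved

    def test_instrument_spans_range_within_strata(self, small_cohort, small_grs):
        """Each final stratum contains low- and high-score individuals, unlike
        naive exposure deciles."""
        t = small_cohort.table
        score = np.asarray(small_grs, float)
        a = nonlinear.doubly_ranked_strata(score, t["exposure"], 10)
        lo, hi = np.quantile(score, [0.2, 0.8])
        for k in range(1, 11):
            s_k = score[a == k]
            assert s_k.min() < lo and s_k.max() > hi

    def test_confounder_independence_contrast(self):
        """Within-stratum score-confounder p-values: uniform for doubly-ranked,
        collapsed to ~0 for naive exposure deciles (collider bias)."""
        from mrdose.experiments import stratification_balance

        res = stratification_balance(n_reps=25, n=2000, seed=5)
        assert res["doubly_ranked_rejection_rate"] < 0.12
        assert res["naive_rejection_rate"] > 0.5


class TestStratumLace:
    def test_single_stratum_reduces_to_whole_sample_ratio(self, small_cohort, small_grs):
        t = small_cohort.table
        a = np.ones(small_cohort.n, int)
        strata = nonlinear.stratum_lace(
            small_grs, t["exposure"], a, t["disease"], model="logistic"
        )
        gx = assoc.linear_assoc(t["exposure"], small_grs)
        gy = assoc.logistic_assoc(t["disease"], small_grs)
        whole = linear.ratio_estimate(gy, gx)
        assert strata[0].theta_k == pytest.approx(whole.theta, abs=1e-9)
        assert strata[0].se_k == pytest.approx(whole.se, abs=1e-9)

    def test_homogeneous_effect_gives_homogeneous_strata(self):
        """Linear curve: every LACE within 2 se of truth-ish and Q not rejecting."""
        cfg = SimConfig(
            n_individuals=8000, n_variants=40,
            causal_curve=CausalCurve("linear", (0.5,)), seed=50,
        )
        cohort = simulate_cohort(cfg)
        t = cohort.table
        score = ins.build_grs(
            cohort.dosages,
            [ins.VariantWeight(v, "A", float(w)) for v, w in cohort.true_weights.items()],
        )
        a = nonlinear.doubly_ranked_strata(score, t["exposure"], 10)
        strata = nonlinear.stratum_lace(score, t["exposure"], a, t["disease"], model="logistic")
        assert sum(s.usable for s in strata) == 10
        q, p = nonlinear.cochran_q(strata)
        assert p > 0.01
        assert sum(abs(s.theta_k - 0.5) < 2.5 * s.se_k for s in strata) >= 8

    def test_quadratic_curve_produces_trend_in_lace(self):
        """Convex curve: LACE increases with stratum exposure (rank correlation)."""
        from scipy.stats import spearmanr

        agree = 0
        for seed in range(5):
            cfg = SimConfig(
                n_individuals=8000, n_variants=40,
                causal_curve=CausalCurve("quadratic", (0.4, 0.25)), seed=60 + seed,
            )
            cohort = simulate_cohort(cfg)
            t = cohort.table
            score = ins.build_grs(
                cohort.dosages,
                [ins.VariantWeight(v, "A", float(w)) for v, w in cohort.true_weights.items()],
            )
            a = nonlinear.doubly_ranked_strata(score, t["exposure"], 10)
            strata = nonlinear.stratum_lace(
                score, t["exposure"], a, t["disease"], model="logistic"
            )
            xb = [s.xbar_k for s in strata if s.usable]
            th = [s.theta_k for s in strata if s.usable]
            agree += spearmanr(xb, th).statistic > 0
        assert agree >= 4

    def test_failed_stratum_flagged_missing(self):
        rng = np.random.default_rng(51)
        n = 200
        score = rng.standard_normal(n)
        expo = 0.4 * score + rng.standard_normal(n)
        disease = np.zeros(n)
        a = np.r_[np.ones(100, int), np.full(100, 2, int)]
        disease[:100] = rng.binomial(1, 0.3, 100)  # stratum 2 has zero events
        with pytest.warns(UserWarning, match="stratum 2"):
            strata = nonlinear.stratum_lace(score, expo, a, disease, model="logistic")
        assert strata[0].usable and not strata[1].usable


class TestFPMetaRegress:
    def test_constant_lace_gives_linear_curve(self):
        strata = _flat_strata(theta=0.4)
        fit = nonlinear.fp_meta_regress(strata)
        assert fit.powers == (1.0,)
        grid = fit.curve["x"].to_numpy()
        np.testing.assert_allclose(
            fit.curve["effect"], 0.4 * (grid - fit.reference_x), atol=1e-6
        )
        assert fit.p_fp_nonlinearity == 1.0

    def test_quadratic_oracle_recovery(self):
        """Strata from a known quadratic with tiny noise: curve within 1%."""
        from mrdose.experiments import curve_recovery_error

        res = curve_recovery_error(coefficients=(0.3, 0.08), noise_sd=1e-4, seed=0)
        assert res["max_relative_error"] < 0.01
        assert res["effect_at_reference"] == 0.0

    def test_power_one_equals_independent_wls(self):
        """Degree-1 p=1 basis reduces to constant-derivative WLS: slope equals
        the closed-form weighted mean of theta_k."""
        rng = np.random.default_rng(52)
        strata = _flat_strata(theta=0.3, se=0.1, rng=rng)
        th = np.array([s.theta_k for s in strata])
        w = np.array([1 / s.se_k**2 for s in strata])
        oracle = (w * th).sum() / w.sum()
        fit = nonlinear.fp_meta_regress(strata, degree_max=1)
        # under a flat profile the selected model may be any power; force p=1
        D, _ = nonlinear._fp_bases((1.0,), np.array([s.xbar_k for s in strata]))
        coef, cov, ll = nonlinear._wls_loglik(th, np.array([s.se_k for s in strata]), D)
        assert coef[0] == pytest.approx(oracle, abs=1e-12)

    def test_negative_exposures_shifted(self):
        strata = _flat_strata(theta=0.4, lo=-2.0, hi=2.0)
        fit = nonlinear.fp_meta_regress(strata)
        assert fit.shift == pytest.approx(3.0)
        assert fit.curve["effect"].iloc[0] == pytest.approx(
            0.4 * (strata[0].xbar_k - fit.reference_x), abs=1e-6
        )

    def test_no_exposure_spread_rejected(self):
        strata = [StratumEstimate(k, 10, 1.0, 0.1, 0.1) for k in range(1, 5)]
        with pytest.raises(ValueError, match="spread"):
            nonlinear.fp_meta_regress(strata)

    def test_too_few_strata_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            nonlinear.fp_meta_regress(_flat_strata(S=2))


class TestTrendAndNonlinearityTests:
    def test_flat_profile_trend_p_near_one(self):
        assert nonlinear.trend_test(_flat_strata(theta=0.25)) > 0.99

    def test_perfect_trend_p_near_zero(self):
        strata = [
            StratumEstimate(k + 1, 100, x, 0.1 + 0.3 * x, 1e-5)
            for k, x in enumerate(np.linspace(1, 3, 8))
        ]
        assert nonlinear.trend_test(strata) < 1e-10

    def test_strong_quadratic_fp_p_near_zero(self):
        xb = np.linspace(0.5, 3.5, 10)
        strata = [
            StratumEstimate(k + 1, 100, float(x), 0.1 + 0.4 * x, 1e-4)
            for k, x in enumerate(xb)
        ]
        fit = nonlinear.fp_meta_regress(strata)
        assert fit.powers != (1.0,)
        assert fit.p_fp_nonlinearity < 1e-8

    def test_calibration_under_linear_truth(self):
        """Both tests reject at ~nominal rate under a linear causal curve."""
        from mrdose.experiments import nonlinearity_calibration

        res = nonlinearity_calibration(n_reps=60, n=3000, n_variants=30, seed=9)
        assert res["trend_rejection_rate"] <= 0.15
        assert res["fp_rejection_rate"] <= 0.15


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(53)
    return nonlinear.fp_meta_regress(_flat_strata(theta=0.4, se=0.02, rng=rng))


class TestExportCurve:

    def test_reference_effect_zero_with_zero_width_ci(self, fit):
        tab = nonlinear.export_curve(fit, grid=np.array([fit.reference_x]))
        assert tab["effect"].iloc[0] == 0.0
        assert tab["ci_low"].iloc[0] == 0.0 and tab["ci_high"].iloc[0] == 0.0

    def test_ci_brackets_effect_pointwise(self, fit):
        tab = nonlinear.export_curve(fit)
        assert (tab["ci_low"] <= tab["effect"]).all()
        assert (tab["effect"] <= tab["ci_high"]).all()

    def test_exponentiated_export_is_elementwise_exp(self, fit):
        log_tab = nonlinear.export_curve(fit)
        exp_tab = nonlinear.export_curve(fit, exponentiate=True)
        np.testing.assert_allclose(exp_tab["effect"], np.exp(log_tab["effect"]), atol=1e-12)
        np.testing.assert_allclose(exp_tab["ci_low"], np.exp(log_tab["ci_low"]), atol=1e-12)

    def test_extrapolation_warns(self, fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            nonlinear.export_curve(fit, grid=np.array([fit.x_range[1] + 5.0]))
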