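"""Tests of the univariable and multivariable MR estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrdose import assoc, linear
from mrdose.assoc import AssocResult

from conftest import make_summary_stats


def _assoc(beta, se, scale="logOR"):
    return AssocResult(beta=beta, se=se, p=0.5, n=100, scale=scale)


class TestRatio:
    def test_formula(self):
        est = linear.ratio_estimate(_assoc(0.4, 0.1), _assoc(0.2, 0.01, "identity"))
        assert est.theta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)
        assert est.scale == "logOR"

    def test_null_numerator(self):
        est = linear.ratio_estimate(_assoc(0.0, 0.1), _assoc(0.2, 0.01, "identity"))
        assert est.theta == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError, match="instrument"):
            linear.ratio_estimate(_assoc(0.4, 0.1), _assoc(0.0, 0.01, "identity"))

    def test_first_order_se_against_bootstrap_oracle(self):
        """First-order delta se agrees with a parametric bootstrap up to the
        beta_GX-uncertainty correction term (strong instrument regime)."""
        rng = np.random.default_rng(20)
        bgy, segy, bgx, segx = 0.4, 0.05, 0.5, 0.01
        draws = rng.normal(bgy, segy, 100_000) / rng.normal(bgx, segx, 100_000)
        boot_se = draws.std()
        first_order = segy / abs(bgx)
        # second-order correction: theta^2 * segx^2 / bgx^2
        correction = np.sqrt(first_order**2 + (bgy / bgx) ** 2 * segx**2 / bgx**2) - first_order
        assert abs(boot_se - first_order) <= correction * 2 + 1e-4


class TestIVW:
    def test_two_variant_closed_form(self):
        s = make_summary_stats([0.1, 0.2], [0.01, 0.01], [0.2, 0.2], [0.1, 0.1])
        est = linear.ivw(s)
        assert est.theta == pytest.approx(1.2, abs=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(5), abs=1e-12)

    def test_consistency_with_shared_ratio(self):
        bx = np.array([0.1, 0.2, 0.3])
        s = make_summary_stats(bx, bx * 0, 0.7 * bx, np.full(3, 1e-6))
        assert linear.ivw(s).theta == pytest.approx(0.7, abs=1e-9)

    def test_two_identical_variants_reduce_to_ratio(self):
        s = make_summary_stats([0.2, 0.2], [0.01, 0.01], [0.3, 0.3], [0.1, 0.1])
        est = linear.ivw(s)
        ratio = linear.ratio_estimate(_assoc(0.3, 0.1), _assoc(0.2, 0.01, "identity"))
        assert est.theta == pytest.approx(ratio.theta, abs=1e-12)

    def test_single_variant_redirected(self):
        s = make_summary_stats([0.1], [0.01], [0.2], [0.1])
        with pytest.raises(ValueError, match="ratio_estimate"):
            linear.ivw(s)

    def test_equals_precision_weighted_mean_of_ratios(self):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.05, 0.3, 20)
        by = 0.5 * bx + rng.normal(0, 0.02, 20)
        sy = rng.uniform(0.02, 0.08, 20)
        s = make_summary_stats(bx, bx * 0, by, sy)
        w = bx**2 / sy**2
        oracle = np.sum(w * (by / bx)) / w.sum()
        assert linear.ivw(s).theta == pytest.approx(oracle, abs=1e-12)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3])
        s = make_summary_stats(bx, bx * 0, 0.05 + 0.8 * bx, np.full(3, 0.1))
        est = linear.mr_egger(s)
        assert est.theta == pytest.approx(0.8, abs=1e-9)
        assert est.extras["egger_intercept"] == pytest.approx(0.05, abs=1e-9)

    def test_zero_intercept_data_matches_ivw(self):
        rng = np.random.default_rng(22)
        bx = rng.uniform(0.1, 0.5, 50)
        sy = np.full(50, 0.05)
        by = 0.6 * bx + rng.normal(0, 1e-4, 50)
        s = make_summary_stats(bx, bx * 0, by, sy)
        assert linear.mr_egger(s).theta == pytest.approx(linear.ivw(s).theta, abs=0.01)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(23)
        bx = rng.uniform(0.1, 0.5, 30)
        by = 0.03 + 0.4 * bx
        s1 = make_summary_stats(bx, bx * 0, by, np.full(30, 0.05))
        flip = np.ones(30); flip[::3] = -1
        s2 = make_summary_stats(bx * flip, bx * 0, by * flip, np.full(30, 0.05))
        assert linear.mr_egger(s2).theta == pytest.approx(linear.mr_egger(s1).theta, abs=1e-10)

    def test_no_spread_rejected(self):
        s = make_summary_stats([0.2, 0.2, 0.2], [0] * 3, [0.1, 0.2, 0.3], [0.1] * 3)
        with pytest.raises(ValueError, match="spread"):
            linear.mr_egger(s)

    def test_intercept_test_power_under_directional_pleiotropy(self):
        """Intercept 0.1, 50 variants, se_gy=0.02: power above 50% (100 reps)."""
        rng = np.random.default_rng(24)
        hits = 0
        reps = 100
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.3, 50)
            by = 0.1 + 0.3 * bx + rng.normal(0, 0.02, 50)
            s = make_summary_stats(bx, bx * 0, by, np.full(50, 0.02))
            hits += linear.mr_egger(s).extras["egger_intercept_p"] < 0.05
        assert hits / reps > 0.5


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        s = make_summary_stats([1, 1, 1], [0] * 3, [1.0, 2.0, 3.0], [0.1] * 3)
        assert linear.weighted_median(s, n_boot=10).theta == pytest.approx(2.0)

    def test_cumulative_weight_interpolation_oracle(self):
        # ratios (1,2,3), weights (0.5,0.25,0.25) -> 1 + (0.5-0.25)/(0.625-0.25) = 5/3
        sy = np.array([0.1, 0.1 * np.sqrt(2), 0.1 * np.sqrt(2)])
        s = make_summary_stats([1, 1, 1], [0] * 3, [1.0, 2.0, 3.0], sy)
        assert linear.weighted_median(s, n_boot=10).theta == pytest.approx(5 / 3, abs=1e-12)

    def test_breakdown_under_minority_contamination(self):
        """<50% of weight on wildly invalid variants barely moves the estimate."""
        rng = np.random.default_rng(25)
        bx = np.r_[np.full(12, 0.2), np.full(8, 0.2)]
        by = np.r_[0.5 * bx[:12] + rng.normal(0, 0.005, 12), 5.0 * bx[12:]]
        s = make_summary_stats(bx, bx * 0, by, np.full(20, 0.02))
        est = linear.weighted_median(s, n_boot=500, seed=1)
        assert abs(est.theta - 0.5) < 2 * est.se + 0.05

    def test_zero_bx_dropped_with_warning(self):
        s = make_summary_stats([0.0, 1, 1, 1], [0] * 4, [9.9, 1.0, 2.0, 3.0], [0.1] * 4)
        with pytest.warns(UserWarning, match="dropping"):
            est = linear.weighted_median(s, n_boot=10)
        assert est.theta == pytest.approx(2.0)


class TestConMix:
    def test_no_contamination_single_mode(self):
        s = make_summary_stats([1, 1, 1], [0] * 3, [0.5, 0.5, 0.5], [0.01] * 3)
        est = linear.contamination_mixture(s, psi=1.0)
        assert est.theta == pytest.approx(0.5, abs=0.01)
        assert len(est.extras["conmix_modes"]) == 1

    def test_outlier_classified_invalid_matches_bruteforce(self):
        """Estimate ~1 with the theta=5 outlier invalid; profile equals the
        exhaustive enumeration over all 2^3 validity configurations x grid."""
        s = make_summary_stats([1, 1, 1], [0] * 3, [1.0, 1.0, 5.0], [0.05] * 3)
        psi = 3.0
        est = linear.contamination_mixture(s, psi=psi)
        assert est.theta == pytest.approx(1.0, abs=0.02)
        assert est.extras["n_valid"] == 2
        # brute-force oracle over configurations
        ratios, ses = np.array([1.0, 1.0, 5.0]), np.array([0.05] * 3)
        grid = np.linspace(est.ci95[0] - 1, est.ci95[1] + 1, 801)
        best_ll, best_theta = -np.inf, None
        for mask in range(8):
            valid = np.array([(mask >> j) & 1 for j in range(3)], bool)
            for th in grid:
                ll = stats.norm.logpdf(ratios[valid], th, ses[valid]).sum() + stats.norm.logpdf(
                    ratios[~valid], 0.0, np.sqrt(psi**2 + ses[~valid] ** 2)
                ).sum()
                if ll > best_ll:
                    best_ll, best_theta = ll, th
        assert est.theta == pytest.approx(best_theta, abs=0.02)

    def test_invalid_likelihood_monotone_in_psi(self):
        ratios = np.array([0.5, 1.0, 2.0])
        lls = [
            stats.norm.logpdf(ratios, 0.0, np.sqrt(psi**2 + 0.05**2)).sum()
            for psi in (3.0, 5.0, 10.0)
        ]
        assert lls[0] > lls[1] > lls[2]  # wider psi flattens the invalid density

    def test_degenerate_grid_rejected(self):
        s = make_summary_stats([1, 1], [0] * 2, [0.5, 0.5], [0.1] * 2)
        with pytest.raises(ValueError, match="3 variants"):
            linear.contamination_mixture(s)


class TestMVMR:
    def test_degenerate_second_score_reduces_to_univariable(self):
        rng = np.random.default_rng(26)
        n = 4000
        s1 = rng.standard_normal(n)
        x1 = s1 * 0.4 + rng.standard_normal(n)
        y = 0.5 * x1 + rng.standard_normal(n)
        scores = pd.DataFrame({"x1": s1, "x2": np.zeros(n)})
        exposures = pd.DataFrame({"x1": x1, "x2": rng.standard_normal(n)})
        with pytest.warns(UserWarning, match="unidentified"):
            mv = linear.mvmr_grs(scores, exposures, y, model="linear")
        uni = linear.ratio_estimate(
            assoc.linear_assoc(y, s1), assoc.linear_assoc(x1, s1)
        )
        assert mv.exposures == ["x1"]
        assert mv.theta[0] == pytest.approx(uni.theta, abs=1e-9)

    def test_recovers_direct_effects(self):
        from mrdose.simulate import SimConfig, simulate_mvmr_cohort
        from mrdose import instruments as ins

        cfg = SimConfig(n_individuals=20000, n_variants=100, seed=1)
        cohort, w2, _ = simulate_mvmr_cohort(cfg, (0.5, 0.0), 0.5)
        t = cohort.table
        mk = lambda w: [ins.VariantWeight(v, "A", float(x)) for v, x in w.items()]
        scores = pd.DataFrame(
            {
                "x1": ins.build_grs(cohort.dosages, mk(cohort.true_weights)),
                "x2": ins.build_grs(cohort.dosages, mk(w2)),
            }
        )
        exposures = pd.DataFrame({"x1": t["exposure"], "x2": t["exposure2"]})
        mv = linear.mvmr_grs(scores, exposures, t["disease"], model="logistic")
        assert abs(mv.theta[0] - 0.5) < 2 * mv.se[0]
        assert abs(mv.theta[1] - 0.0) < 2 * mv.se[1]
        assert (mv.conditional_f > 10).all()

    def test_swap_equivariance(self):
        rng = np.random.default_rng(27)
        n = 3000
        S = rng.standard_normal((n, 2))
        X = S @ np.array([[0.5, 0.2], [0.1, 0.6]]) + rng.standard_normal((n, 2))
        y = X @ np.array([0.3, -0.2]) + rng.standard_normal(n)
        scores = pd.DataFrame(S, columns=["a", "b"])
        exposures = pd.DataFrame(X, columns=["a", "b"])
        mv1 = linear.mvmr_grs(scores, exposures, y, model="linear")
        mv2 = linear.mvmr_grs(
            scores[["b", "a"]], exposures[["b", "a"]], y, model="linear"
        )
        np.testing.assert_allclose(mv1.theta, mv2.theta[::-1], atol=1e-9)

    def test_singular_score_exposure_matrix_rejected(self):
        rng = np.random.default_rng(28)
        n = 500
        s = rng.standard_normal(n)
        scores = pd.DataFrame({"a": s, "b": 2 * s + 1e-12 * rng.standard_normal(n)})
        x = s + rng.standard_normal(n)
        exposures = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="identified"):
            linear.mvmr_grs(scores, exposures, rng.standard_normal(n), model="linear")


class TestConditionalF:
    def test_orthogonal_instruments_near_marginal_f(self):
        from mrdose import instruments as ins

        rng = np.random.default_rng(29)
        n = 20000
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        x1 = 0.35 * s1 + rng.standard_normal(n)
        x2 = 0.35 * s2 + rng.standard_normal(n)
        cf = linear.conditional_f(
            pd.DataFrame({"x1": s1, "x2": s2}), pd.DataFrame({"x1": x1, "x2": x2})
        )
        marg1 = ins.score_strength(s1, x1).f_stat
        marg2 = ins.score_strength(s2, x2).f_stat
        assert cf[0] == pytest.approx(marg1, rel=0.10)
        assert cf[1] == pytest.approx(marg2, rel=0.10)
        assert (cf > 10).all()  # weak-instrument flag rule at threshold 10

    def test_collinear_scores_give_conditional_f_near_zero(self):
        rng = np.random.default_rng(30)
        n = 5000
        s = rng.standard_normal(n)
        scores = pd.DataFrame({"x1": s, "x2": s * 1.0})
        x1 = 0.4 * s + rng.standard_normal(n)
        x2 = 0.8 * s + rng.standard_normal(n)
        cf = linear.conditional_f(scores, pd.DataFrame({"x1": x1, "x2": x2}))
        assert (cf < 1.0).all()

    def test_single_exposure_redirected(self):
        with pytest.raises(ValueError, match="score_strength"):
            linear.conditional_f(
                pd.DataFrame({"a": [1.0, 2, 3]}), pd.DataFrame({"a": [1.0, 2, 3]})
            )


class TestSubgroupZ:
    def test_identical_estimates(self):
        e = linear.MREstimate(0.3, 0.1, "logOR", "ratio")
        z, p = linear.subgroup_difference_z(e, e)
        assert z == 0.0 and p == 1.0

    def test_scale_mismatch_rejected(self):
        e1 = linear.MREstimate(0.3, 0.1, "logOR", "ratio")
        e2 = linear.MREstimate(0.3, 0.1, "logHR", "ratio")
        with pytest.raises(ValueError, match="scale"):
            linear.subgroup_difference_z(e1, e2)

    def test_closed_form(self):
        e1 = linear.MREstimate(0.5, 0.1, "logOR", "ratio")
        e2 = linear.MREstimate(0.2, 0.2, "logOR", "ratio")
        z, p = linear.subgroup_difference_z(e1, e2)
        assert z == pytest.approx(0.3 / np.sqrt(0.05))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))


class TestExponentiate:
    def test_null_or(self):
        e = linear.MREstimate(0.0, 0.1, "logOR", "ratio")
        out = linear.exponentiate(e)
        assert out.point == pytest.approx(1.0)
        assert out.ci95[0] < 1.0 < out.ci95[1]

    def test_exact_or_two(self):
        e = linear.MREstimate(np.log(2.0), 0.0, "logHR", "ratio")
        out = linear.exponentiate(e)
        assert out.point == pytest.approx(2.0, abs=1e-12)
        assert out.scale == "HR"

    def test_round_trip(self):
        e = linear.MREstimate(0.37, 0.08, "logOR", "ivw")
        out = linear.exponentiate(e, sd_units=1.0)
        assert np.log(out.point) == pytest.approx(e.theta, abs=1e-14)
        assert np.log(out.ci95[0]) == pytest.approx(e.ci95[0], abs=1e-14)

    def test_identity_scale_rejected(self):
        with pytest.raises(ValueError):
            linear.exponentiate(linear.MREstimate(0.1, 0.1, "identity", "ratio"))


@pytest.fixture(scope="module")
def null_pleiotropy_stats():
    rng = np.random.default_rng(31)
    bx = rng.uniform(0.05, 0.3, 50)
    sy = np.full(50, 0.04)
    by = 0.5 * bx + rng.normal(0, 0.04, 50)
    return make_summary_stats(bx, np.full(50, 0.01), by, sy)


class TestEstimatorInvariants:
    """Shared properties across the sensitivity-estimator suite."""

    @pytest.mark.parametrize(
        "estimator",
        [linear.ivw, linear.mr_egger, linear.weighted_median, linear.contamination_mixture],
        ids=["ivw", "egger", "wmedian", "conmix"],
    )
    def test_recover_true_effect_without_pleiotropy(self, estimator, null_pleiotropy_stats):
        est = estimator(null_pleiotropy_stats)
        assert abs(est.theta - 0.5) < 2 * max(est.se, 0.02)

    @pytest.mark.parametrize(
        "estimator",
        [linear.ivw, linear.mr_egger, linear.weighted_median, linear.contamination_mixture],
        ids=["ivw", "egger", "wmedian", "conmix"],
    )
    def test_sign_flip_invariance(self, estimator, null_pleiotropy_stats):
        s = null_pleiotropy_stats
        flip = np.ones(len(s)); flip[::2] = -1
        flipped = make_summary_stats(
            s.beta_gx * flip, s.se_gx, s.beta_gy * flip, s.se_gy
        )
        assert estimator(flipped).theta == pytest.approx(
            estimator(s).theta, abs=5e-3
        )
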