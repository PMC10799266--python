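"""Replicated simulation experiments used for validity checks.

These experiments define the package's own evidence that the nonlinear MR
machinery behaves as advertised: type-I-error calibration of the trend and
fractional-polynomial nonlinearity tests under a truly linear causal curve,
confounder-independence of the instrument within doubly-ranked strata (and
its failure under naive exposure stratification), and recovery of a known
curve from near-noiseless strata. They are deliberately modest in size so a
full run stays in the minutes range on one CPU; the same code backs the test
suite and the acceptance script.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import instruments, linear, nonlinear
from .simulate import CausalCurve, SimConfig, simulate_cohort, true_curve

__all__ = [
    "nonlinearity_calibration",
    "stratification_balance",
    "curve_recovery_error",
    "linear_recovery_suite",
]


def _grs(cohort):
    w = [
        instruments.VariantWeight(v, "A", float(x))
        for v, x in cohort.true_weights.items()
    ]
    return instruments.build_grs(cohort.dosages, w)


def nonlinearity_calibration(
    n_reps: int = 500,
    n: int = 5000,
    n_variants: int = 50,
    n_strata: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rates of the trend and FP-nonlinearity tests under linearity.

    Each replicate simulates a cohort with a *linear* causal curve (log-odds
    slope 0.5 per exposure SD), stratifies it with the doubly-ranked method,
    forms stratum-specific logistic LACE estimates, and runs both tests at
    level ``alpha``. Both should reject at close to the nominal rate.
    """
    root = np.random.SeedSequence(seed)
    rej_trend = rej_fp = used = 0
    for child in root.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = SimConfig(
            n_individuals=n,
            n_variants=n_variants,
            causal_curve=CausalCurve("linear", (0.5,)),
            seed=rep_seed,
        )
        cohort = simulate_cohort(cfg)
        t = cohort.table
        score = _grs(cohort)
        assignment = nonlinear.doubly_ranked_strata(score, t["exposure"], n_strata)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strata = nonlinear.stratum_lace(
                score, t["exposure"], assignment, t["disease"], model="logistic"
            )
            if sum(s.usable for s in strata) < n_strata:
                continue
            fit = nonlinear.fp_meta_regress(strata)
        used += 1
        rej_trend += fit.p_trend < alpha
        rej_fp += fit.p_fp_nonlinearity < alpha
    return {
        "trend_rejection_rate": rej_trend / used,
        "fp_rejection_rate": rej_fp / used,
        "n_reps_used": used,
    }


def stratification_balance(
    n_reps: int = 100,
    n: int = 2000,
    n_variants: int = 50,
    n_strata: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Instrument-confounder independence within strata, by stratification method.

    For each replicate, the regression of the hidden confounder U on the
    instrument score is fitted within every stratum. Doubly-ranked strata
    preserve the randomization: those p-values are uniform (rejection at
    ``alpha`` stays nominal). Naive exposure deciles condition on a collider
    (the exposure), inducing a within-stratum score-U association and an
    inflated rejection rate. Returns the two rejection rates and the pooled
    doubly-ranked p-values for a uniformity check.
    """
    root = np.random.SeedSequence(seed)
    ps_dr, ps_naive = [], []
    for child in root.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = SimConfig(n_individuals=n, n_variants=n_variants, seed=rep_seed)
        cohort = simulate_cohort(cfg)
        t = cohort.table
        score = _grs(cohort)
        x = t["exposure"].to_numpy()
        u = t["confounder"].to_numpy()
        dr = nonlinear.doubly_ranked_strata(score, x, n_strata)
        ranks = np.argsort(np.argsort(x))
        naive = np.minimum(ranks * n_strata // len(x), n_strata - 1) + 1
        ps_dr.extend(nonlinear.within_stratum_confounder_assoc(score, u, dr))
        ps_naive.extend(nonlinear.within_stratum_confounder_assoc(score, u, naive))
    ps_dr, ps_naive = np.asarray(ps_dr), np.asarray(ps_naive)
    return {
        "doubly_ranked_rejection_rate": float((ps_dr < alpha).mean()),
        "naive_rejection_rate": float((ps_naive < alpha).mean()),
        "doubly_ranked_pvalues": ps_dr,
    }


def curve_recovery_error(
    coefficients: tuple = (0.3, 0.08),
    n_strata: int = 10,
    noise_sd: float = 1e-4,
    seed: int = 0,
) -> dict:
    """Sup-norm relative error of the FP curve against a known quadratic.

    Strata are generated directly from the quadratic causal curve
    h'(x) = c0 + 2*c1*x at stratum means spread over ~2.4 exposure SDs, with
    near-noiseless LACE values (``noise_sd``), then fitted by FP
    meta-regression. Returns the fitted-vs-true comparison on an interior
    grid: max |fit - true| / max |true| and the curve value at the median
    reference (exactly 0 by construction of the contrast).
    """
    rng = np.random.default_rng(seed)
    curve = CausalCurve("quadratic", coefficients)
    xbar = np.linspace(-1.2, 1.2, n_strata)
    c0, c1 = coefficients
    deriv = c0 + 2 * c1 * xbar
    strata = [
        nonlinear.StratumEstimate(
            k=k + 1,
            n_k=1000,
            xbar_k=float(xbar[k]),
            theta_k=float(deriv[k] + rng.normal(0.0, noise_sd)),
            se_k=noise_sd,
        )
        for k in range(n_strata)
    ]
    reference = float(np.median(xbar))
    fit = nonlinear.fp_meta_regress(strata, reference_x=reference)
    grid = np.linspace(xbar[1], xbar[-2], 81)  # interior of the stratum range
    fitted = nonlinear.export_curve(fit, grid=grid)["effect"].to_numpy()
    cfg = SimConfig(causal_curve=curve)
    truth = curve(grid) - curve(reference)
    rel_err = float(np.max(np.abs(fitted - truth)) / np.max(np.abs(truth)))
    at_ref = float(nonlinear.export_curve(fit, grid=np.array([reference]))["effect"][0])
    return {
        "max_relative_error": rel_err,
        "effect_at_reference": at_ref,
        "powers": fit.powers,
        "true_curve": truth,
        "fitted_curve": fitted,
    }


def linear_recovery_suite(
    n: int = 20000, n_variants: int = 50, true_effect: float = 0.5, seed: int = 0
) -> dict:
    """All five univariable estimators on one simulated cohort.

    Simulates a linear log-OR effect of ``true_effect`` per exposure SD and
    returns each estimator's MREstimate: the GRS ratio estimate plus the
    four summary-statistic sensitivity estimators fed by per-variant
    association scans.
    """
    from . import assoc

    cfg = SimConfig(
        n_individuals=n,
        n_variants=n_variants,
        causal_curve=CausalCurve("linear", (true_effect,)),
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    t = cohort.table
    score = _grs(cohort)
    gx = assoc.linear_assoc(t["exposure"], score)
    gy = assoc.logistic_assoc(t["disease"], score)
    out = {"ratio": linear.ratio_estimate(gy, gx)}
    gx_scan = assoc.variant_associations(cohort.dosages, t["exposure"], "linear")
    gy_scan = assoc.variant_associations(cohort.dosages, t["disease"], "logistic")
    stats = linear.SummaryStats(
        list(cohort.dosages.columns),
        gx_scan["beta"].to_numpy(),
        gx_scan["se"].to_numpy(),
        gy_scan["beta"].to_numpy(),
        gy_scan["se"].to_numpy(),
    )
    out["ivw"] = linear.ivw(stats)
    out["egger"] = linear.mr_egger(stats)
    out["weighted_median"] = linear.weighted_median(stats, seed=seed)
    out["conmix"] = linear.contamination_mixture(stats)
    return out
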