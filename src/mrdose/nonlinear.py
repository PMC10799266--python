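"""Nonlinear Mendelian randomization: doubly-ranked strata and fractional
polynomial dose-response curves.

The population is stratified by the *doubly ranked* method: sort by the
instrument score, cut consecutively into pre-strata of size S, rank each
pre-stratum by exposure, and send the individual with exposure rank j to
final stratum j. Unlike naive exposure stratification, the instrument spans
its full range within every final stratum and remains independent of
confounders there, so a stratum-specific ratio estimate (the localized
average causal effect, LACE) is valid in each stratum.

The LACE values theta_k are interpreted as the derivative of the causal
curve near the stratum mean exposure xbar_k and meta-regressed, with weights
1/se_k^2, on the derivative basis of fractional polynomials with powers from
P = {-2, -1, -0.5, 0, 0.5, 1, 2} (0 = log; repeated powers take the
log-modified basis). The best model by weighted log-likelihood is
analytically integrated into an effect curve relative to a reference
exposure (the sample median by convention). A trend test (meta-regression of
theta_k on xbar_k) and a fractional-polynomial nonlinearity test (best model
vs the linear model) accompany the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assoc import linear_assoc, logistic_assoc, cox_assoc

__all__ = [
    "StratumEstimate",
    "FPFit",
    "FP_POWERS",
    "doubly_ranked_strata",
    "stratum_lace",
    "fp_meta_regress",
    "trend_test",
    "fp_nonlinearity_test",
    "export_curve",
    "cochran_q",
    "within_stratum_confounder_assoc",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


@dataclass
class StratumEstimate:
    k: int
    n_k: int
    xbar_k: float
    theta_k: float
    se_k: float

    @property
    def usable(self) -> bool:
        return np.isfinite(self.theta_k) and np.isfinite(self.se_k) and self.se_k > 0


@dataclass
class FPFit:
    degree: int
    powers: tuple
    coefficients: np.ndarray
    covariance: np.ndarray
    p_trend: float
    p_fp_nonlinearity: float
    curve: pd.DataFrame
    reference_x: float
    shift: float
    loglik: float
    scale: str = "logOR"
    x_range: tuple = (np.nan, np.nan)
    extras: dict = field(default_factory=dict)


def doubly_ranked_strata(score, exposure, n_strata: int) -> np.ndarray:
    """Doubly-ranked stratum assignment (1..S per individual).

    Individuals are ordered by instrument score (ties broken by exposure,
    then position), cut into consecutive pre-strata of size S, and ranked by
    exposure within each pre-stratum (ties broken by score, then position);
    exposure rank j maps to final stratum j. A final incomplete pre-stratum
    of size r sends its members, in exposure order, to strata 1..r, so
    stratum sizes differ by at most one and are exactly n/S when S | n.
    """
    score = np.asarray(score, float)
    exposure = np.asarray(exposure, float)
    n = len(score)
    S = int(n_strata)
    if S < 1:
        raise ValueError("n_strata must be >= 1")
    if S == 1:
        return np.ones(n, dtype=int)
    if n < S * S:
        raise ValueError(
            f"too few individuals for doubly ranked stratification (n={n} < S^2={S * S})"
        )
    idx = np.arange(n)
    order = np.lexsort((idx, exposure, score))
    assignment = np.empty(n, dtype=int)
    for start in range(0, n, S):
        block = order[start : start + S]
        sub = block[np.lexsort((block, score[block], exposure[block]))]
        assignment[sub] = np.arange(1, len(sub) + 1)
    return assignment


def stratum_lace(
    score,
    exposure,
    assignment,
    outcome,
    model: str = "linear",
    covariates: pd.DataFrame | None = None,
    entry_age=None,
    event=None,
    adjustment_set: str = "custom",
) -> list[StratumEstimate]:
    """Per-stratum ratio (LACE) estimates on the raw exposure scale.

    Within each stratum the gene-exposure association is a linear regression
    of the *untransformed* exposure on the score (no rank-normalization in
    the nonlinear analysis) and the gene-outcome association uses ``model``
    ('linear', 'logistic', or 'cox' with ``outcome`` = exit age plus
    ``entry_age``/``event``). Strata where a fit fails (e.g. no events) are
    flagged missing with a warning and excluded downstream.
    """
    score = np.asarray(score, float)
    exposure = np.asarray(exposure, float)
    assignment = np.asarray(assignment, int)
    out = []
    for k in sorted(np.unique(assignment)):
        m = assignment == k
        covs_k = covariates.loc[m].reset_index(drop=True) if covariates is not None else None
        try:
            gx = linear_assoc(exposure[m], score[m], covs_k)
            if gx.beta == 0:
                raise ZeroDivisionError("null gene-exposure association")
            if model == "linear":
                gy = linear_assoc(np.asarray(outcome, float)[m], score[m], covs_k)
            elif model == "logistic":
                gy = logistic_assoc(np.asarray(outcome, float)[m], score[m], covs_k)
            elif model == "cox":
                gy = cox_assoc(
                    np.asarray(outcome, float)[m],
                    np.asarray(event)[m],
                    score[m],
                    covs_k,
                    entry_age=None if entry_age is None else np.asarray(entry_age, float)[m],
                )
            else:
                raise ValueError(f"unknown model {model!r}")
            theta, se = gy.beta / gx.beta, gy.se / abs(gx.beta)
        except (ValueError, ZeroDivisionError, RuntimeError) as err:
            warnings.warn(f"stratum {k}: estimate missing ({err})")
            theta, se = np.nan, np.nan
        out.append(
            StratumEstimate(
                k=int(k),
                n_k=int(m.sum()),
                xbar_k=float(exposure[m].mean()),
                theta_k=float(theta),
                se_k=float(se),
            )
        )
    return out


# ---------------------------------------------------------------------------
# fractional polynomial machinery (on shifted, strictly positive exposure)


def _fp_bases(powers: tuple, x: np.ndarray):
    """(derivative basis, antiderivative terms) for a power multiset.

    The causal curve is h(x) = sum_i c_i T_i(x) with T the antiderivative
    terms; the LACE is modelled on the derivative basis dT_i/dx. Repeated
    powers use the log-modified second term T = x^p ln x ((ln x)^2 for p=0).
    """
    x = np.asarray(x, float)
    lx = np.log(x)

    def term(p):
        return lx.copy() if p == 0 else x**p

    def dterm(p):
        return 1.0 / x if p == 0 else p * x ** (p - 1)

    if len(powers) == 1:
        (p,) = powers
        return np.column_stack([dterm(p)]), np.column_stack([term(p)])
    p, q = powers
    if p != q:
        return (
            np.column_stack([dterm(p), dterm(q)]),
            np.column_stack([term(p), term(q)]),
        )
    if p == 0:
        return (
            np.column_stack([1.0 / x, 2.0 * lx / x]),
            np.column_stack([lx, lx**2]),
        )
    return (
        np.column_stack([p * x ** (p - 1), x ** (p - 1) * (p * lx + 1.0)]),
        np.column_stack([x**p, x**p * lx]),
    )


def _wls_loglik(theta, se, D):
    """Weighted LS fit of theta on derivative basis D with known variances."""
    w = 1.0 / se**2
    WD = D * w[:, None]
    A = D.T @ WD
    if np.linalg.cond(A) > 1e12:
        return None
    coef = np.linalg.solve(A, WD.T @ theta)
    resid = theta - D @ coef
    ll = -0.5 * float((w * resid**2).sum() + np.sum(np.log(2 * np.pi * se**2)))
    cov = np.linalg.inv(A)
    return coef, cov, ll


def _candidate_powersets(degree_max: int):
    """Candidates in preference order: lower degree first, then closeness to p=1."""
    deg1 = sorted([(p,) for p in FP_POWERS], key=lambda t: (abs(t[0] - 1), t[0]))
    if degree_max == 1:
        return deg1
    deg2 = sorted(
        [(p, q) for i, p in enumerate(FP_POWERS) for q in FP_POWERS[i:]],
        key=lambda t: (abs(t[0] - 1) + abs(t[1] - 1), t),
    )
    return deg1 + deg2


def _usable(strata):
    xs = np.array([s.xbar_k for s in strata if s.usable])
    th = np.array([s.theta_k for s in strata if s.usable])
    se = np.array([s.se_k for s in strata if s.usable])
    dropped = sum(not s.usable for s in strata)
    if dropped:
        warnings.warn(f"excluding {dropped} stratum/strata with missing estimates")
    return xs, th, se


def fp_meta_regress(
    strata: list[StratumEstimate],
    degree_max: int = 2,
    reference_x: float | None = None,
    grid=None,
    scale: str = "logOR",
    n_grid: int = 101,
) -> FPFit:
    """Fractional-polynomial meta-regression of stratum LACE estimates.

    Fits every candidate power set (degree 1 and, if ``degree_max`` = 2,
    unordered pairs with log-modified repeats) by weighted least squares of
    theta_k on the derivative basis at xbar_k, selects the maximum weighted
    log-likelihood (ties toward lower degree, then powers nearer p=1),
    integrates the fitted derivative analytically into an effect curve
    relative to ``reference_x`` (default: median of xbar_k), and attaches
    pointwise 95% CIs from the coefficient covariance. Exposures are shifted
    by 1 - min(xbar) when min(xbar) <= 0 before powers are applied; the
    shift is inverted on the output grid.
    """
    xs, th, se = _usable(strata)
    if len(xs) < 3:
        raise ValueError("need >= 3 usable strata")
    if np.ptp(xs) == 0:
        raise ValueError("no exposure spread: all stratum means identical")
    if degree_max not in (1, 2):
        raise ValueError("degree_max must be 1 or 2")

    shift = 0.0 if xs.min() > 0 else 1.0 - xs.min()
    xshift = xs + shift

    best = None
    for powers in _candidate_powersets(degree_max):
        D, _ = _fp_bases(powers, xshift)
        fit = _wls_loglik(th, se, D)
        if fit is None:
            continue
        coef, cov, ll = fit
        if best is None or ll > best[3] + 1e-9:
            best = (powers, coef, cov, ll)
    if best is None:
        raise RuntimeError("no fractional polynomial candidate could be fitted")
    powers, coef, cov, ll = best

    if reference_x is None:
        reference_x = float(np.median(xs))
    if grid is None:
        grid = np.linspace(xs.min(), xs.max(), n_grid)
    grid = np.asarray(grid, float)

    curve = _curve_table(powers, coef, cov, grid, reference_x, shift, scale)

    fit_obj = FPFit(
        degree=len(powers),
        powers=tuple(powers),
        coefficients=coef,
        covariance=cov,
        p_trend=np.nan,
        p_fp_nonlinearity=np.nan,
        curve=curve,
        reference_x=float(reference_x),
        shift=float(shift),
        loglik=ll,
        scale=scale,
        x_range=(float(xs.min()), float(xs.max())),
        extras={"n_strata_used": len(xs)},
    )
    fit_obj.p_trend = trend_test(strata)
    fit_obj.p_fp_nonlinearity = fp_nonlinearity_test(strata, fit_obj)
    return fit_obj


def _curve_table(powers, coef, cov, grid, reference_x, shift, scale):
    g = np.asarray(grid, float) + shift
    if (g <= 0).any():
        raise ValueError("grid (after shift) must be strictly positive")
    _, T = _fp_bases(powers, g)
    _, Tref = _fp_bases(powers, np.array([reference_x + shift]))
    A = T - Tref  # contrast vs reference: effect(x) = A(x) @ coef
    effect = A @ coef
    var = np.einsum("ij,jk,ik->i", A, cov, A)
    half = 1.96 * np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {
            "x": np.asarray(grid, float),
            "effect": effect,
            "ci_low": effect - half,
            "ci_high": effect + half,
            "scale": scale,
            "reference_x": reference_x,
        }
    )


def trend_test(strata: list[StratumEstimate]) -> float:
    """Linear trend in stratum estimates: WLS of theta_k on xbar_k.

    Weighted (1/se_k^2) meta-regression with intercept; returns the normal
    two-sided p-value for the slope (known-variance fixed-effect reference).
    """
    xs, th, se = _usable(strata)
    if len(xs) < 3:
        raise ValueError("trend test needs >= 3 usable strata")
    w = 1.0 / se**2
    X = np.column_stack([np.ones_like(xs), xs])
    WX = X * w[:, None]
    A = X.T @ WX
    coef = np.linalg.solve(A, WX.T @ th)
    cov = np.linalg.inv(A)
    z = coef[1] / np.sqrt(cov[1, 1])
    return float(2 * sps.norm.sf(abs(z)))


def fp_nonlinearity_test(strata: list[StratumEstimate], fit: FPFit) -> float:
    """Does the best fractional polynomial beat the linear model?

    Likelihood-ratio comparison of the selected model against the linear
    (degree-1, power 1) model on the same strata, referred to chi-squared
    with df = extra parameters (1 for a degree-1 model with power != 1,
    counting the selected power; 2 for degree 2). If the best model *is*
    linear, p = 1 by convention.
    """
    if fit.powers == (1.0,) or fit.powers == (1,):
        return 1.0
    xs, th, se = _usable(strata)
    D, _ = _fp_bases((1.0,), xs + fit.shift)
    lin = _wls_loglik(th, se, D)
    if lin is None:
        raise RuntimeError("linear reference model could not be fitted")
    _, _, ll_lin = lin
    lr = max(2.0 * (fit.loglik - ll_lin), 0.0)
    df = 1 if fit.degree == 1 else 2
    return float(sps.chi2.sf(lr, df))


def export_curve(
    fit: FPFit,
    grid=None,
    reference_x: float | None = None,
    exponentiate: bool = False,
) -> pd.DataFrame:
    """Tidy dose-response curve table (x, effect, ci_low, ci_high, ...).

    Effects are relative to ``reference_x`` (default: the fit's reference,
    itself the sample median by convention), exactly 0 there. With
    ``exponentiate`` the effect columns are exponentiated elementwise (OR/HR
    vs reference). Grid points outside the observed stratum-mean range
    trigger an extrapolation warning.
    """
    if grid is None:
        grid = fit.curve["x"].to_numpy()
    grid = np.asarray(grid, float)
    if reference_x is None:
        reference_x = fit.reference_x
    lo, hi = fit.x_range
    if np.isfinite(lo) and ((grid < lo).any() or (grid > hi).any()):
        warnings.warn("extrapolation: grid extends beyond the observed exposure range")
    tab = _curve_table(
        fit.powers, fit.coefficients, fit.covariance, grid, reference_x, fit.shift, fit.scale
    )
    if exponentiate:
        for col in ("effect", "ci_low", "ci_high"):
            tab[col] = np.exp(tab[col])
        tab["scale"] = {"logOR": "OR", "logHR": "HR"}.get(fit.scale, "exp")
    return tab


def cochran_q(strata: list[StratumEstimate]) -> tuple:
    """Cochran's Q across stratum estimates and its chi-squared p-value."""
    _, th, se = _usable(strata)
    w = 1.0 / se**2
    pooled = (w * th).sum() / w.sum()
    Q = float((w * (th - pooled) ** 2).sum())
    return Q, float(sps.chi2.sf(Q, len(th) - 1))


def within_stratum_confounder_assoc(score, confounder, assignment) -> np.ndarray:
    """Per-stratum p-values for the instrument-confounder association.

    OLS of the confounder on the score within each stratum. For valid
    stratification (doubly ranked) these are uniform; for naive exposure
    stratification the collider structure makes them concentrate near 0.
    """
    score = np.asarray(score, float)
    confounder = np.asarray(confounder, float)
    assignment = np.asarray(assignment, int)
    ps = []
    for k in sorted(np.unique(assignment)):
        m = assignment == k
        res = linear_assoc(confounder[m], score[m])
        ps.append(res.p)
    return np.array(ps)
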