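"""Univariable and multivariable Mendelian randomization estimators.

The ratio (Wald) estimator on a genetic risk score is the primary method:
theta = beta_GY / beta_GX with a first-order delta-method standard error.
Four summary-statistic sensitivity estimators with different validity
assumptions accompany it:

* IVW — zero-intercept weighted regression of variant-outcome on
  variant-exposure effects (weights 1/se_GY^2), with multiplicative
  random-effects SE inflation when Cochran's Q exceeds its expectation;
* MR-Egger — the same regression with a free intercept; a nonzero intercept
  is the directional-pleiotropy test;
* weighted median — consistent when >= 50% of instrument weight is valid;
* contamination mixture — profile likelihood classifying each variant as
  valid ~ N(theta, se_j^2) or invalid ~ N(0, psi^2 + se_j^2), robust to a
  contaminated instrument set, possibly with multimodal confidence sets.

Multivariable MR estimates direct effects of several exposures from their
GRSs by two-stage regression, with Sanderson-Windmeijer-style conditional F
statistics for per-exposure instrument strength.

All estimation happens on the log-odds / log-hazard scale; use
:func:`exponentiate` for OR/HR presentation per exposure SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult

__all__ = [
    "SummaryStats",
    "MREstimate",
    "MVMRResult",
    "ratio_estimate",
    "ivw",
    "mr_egger",
    "weighted_median",
    "contamination_mixture",
    "mvmr_grs",
    "conditional_f",
    "subgroup_difference_z",
    "exponentiate",
    "estimate_from_ci",
]


@dataclass
class SummaryStats:
    """Per-variant exposure and outcome associations on a shared effect allele."""

    variant_id: list
    beta_gx: np.ndarray
    se_gx: np.ndarray
    beta_gy: np.ndarray
    se_gy: np.ndarray

    def __post_init__(self):
        self.beta_gx = np.asarray(self.beta_gx, float)
        self.se_gx = np.asarray(self.se_gx, float)
        self.beta_gy = np.asarray(self.beta_gy, float)
        self.se_gy = np.asarray(self.se_gy, float)
        lengths = {
            len(self.variant_id),
            self.beta_gx.size,
            self.se_gx.size,
            self.beta_gy.size,
            self.se_gy.size,
        }
        if len(lengths) != 1:
            raise ValueError("summary-statistic vectors must share length and order")
        if (self.se_gx < 0).any() or (self.se_gy <= 0).any():
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.variant_id)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SummaryStats":
        return cls(
            list(df["variant_id"]),
            df["beta_gx"].to_numpy(),
            df["se_gx"].to_numpy(),
            df["beta_gy"].to_numpy(),
            df["se_gy"].to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "beta_gx": self.beta_gx,
                "se_gx": self.se_gx,
                "beta_gy": self.beta_gy,
                "se_gy": self.se_gy,
            }
        )


@dataclass
class MREstimate:
    theta: float
    se: float
    scale: str  # logOR | logHR | identity
    method: str
    ci95: tuple = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci95 is None:
            self.ci95 = (self.theta - 1.96 * self.se, self.theta + 1.96 * self.se)

    @property
    def p(self) -> float:
        if self.se == 0:
            return 0.0 if self.theta != 0 else 1.0
        return 2 * stats.norm.sf(abs(self.theta / self.se))


@dataclass
class MVMRResult:
    exposures: list
    theta: np.ndarray
    se: np.ndarray
    ci95: list
    conditional_f: np.ndarray
    scale: str
    note: str = ""


def ratio_estimate(assoc_gy: AssocResult, assoc_gx: AssocResult) -> MREstimate:
    """Wald ratio: theta = beta_GY / beta_GX, se = se_GY / |beta_GX|.

    First-order delta method (exposure-association uncertainty ignored),
    appropriate when the instrument F statistic is large.
    """
    if assoc_gx.beta == 0:
        raise ZeroDivisionError("weak/null instrument: beta_GX is zero")
    theta = assoc_gy.beta / assoc_gx.beta
    se = assoc_gy.se / abs(assoc_gx.beta)
    return MREstimate(theta=theta, se=se, scale=assoc_gy.scale, method="ratio")


def ivw(stats_: SummaryStats, scale: str = "logOR") -> MREstimate:
    """Inverse-variance weighted estimate.

    Slope of the zero-intercept regression of beta_GY on beta_GX with
    weights 1/se_GY^2 — algebraically the precision-weighted mean of
    per-variant ratios with weights beta_GX^2/se_GY^2. The SE is inflated by
    sqrt(Q/(J-1)) when Cochran's Q exceeds its expectation (multiplicative
    random effects).
    """
    J = len(stats_)
    if J < 2:
        raise ValueError("IVW needs >= 2 variants; use ratio_estimate for one")
    w = 1.0 / stats_.se_gy**2
    bx, by = stats_.beta_gx, stats_.beta_gy
    denom = (w * bx**2).sum()
    theta = (w * bx * by).sum() / denom
    se = 1.0 / np.sqrt(denom)
    Q = (w * (by - theta * bx) ** 2).sum()
    overdispersion = max(1.0, Q / (J - 1))
    se *= np.sqrt(overdispersion)
    return MREstimate(
        theta=float(theta),
        se=float(se),
        scale=scale,
        method="ivw",
        extras={"Q": float(Q), "overdispersion": float(overdispersion), "n_variants": J},
    )


def mr_egger(stats_: SummaryStats, scale: str = "logOR") -> MREstimate:
    """MR-Egger regression with directional-pleiotropy intercept test.

    Variant effects are oriented so beta_GX >= 0, then beta_GY is regressed
    on beta_GX with a free intercept and weights 1/se_GY^2. The intercept
    estimates the average directional pleiotropic effect; its p-value (extras
    ``egger_intercept_p``) tests exclusion-restriction violation. SEs use a
    residual dispersion factor floored at 1.
    """
    J = len(stats_)
    if J < 3:
        raise ValueError("MR-Egger needs >= 3 variants")
    flip = np.where(stats_.beta_gx < 0, -1.0, 1.0)
    bx, by = stats_.beta_gx * flip, stats_.beta_gy * flip
    if np.ptp(bx) == 0:
        raise ValueError("no instrument-strength spread: all beta_GX equal")
    w = 1.0 / stats_.se_gy**2
    X = np.column_stack([np.ones(J), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    dispersion = max(1.0, (w * resid**2).sum() / (J - 2))
    cov = np.linalg.inv(XtWX) * dispersion
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))
    p_inter = 2 * stats.norm.sf(abs(inter / se_inter)) if se_inter > 0 else 0.0
    return MREstimate(
        theta=float(slope),
        se=float(se_slope),
        scale=scale,
        method="egger",
        extras={
            "egger_intercept": float(inter),
            "egger_intercept_se": float(se_inter),
            "egger_intercept_p": float(p_inter),
            "n_variants": J,
        },
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at cumulative midpoints p_j = cum_j - w_j/2."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, v))


def weighted_median(
    stats_: SummaryStats, scale: str = "logOR", n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-variant ratios, weights beta_GX^2 / se_GY^2.

    Consistent when at least half the instrument weight comes from valid
    variants. The SE is a parametric bootstrap (both beta_GX and beta_GY
    perturbed by their SEs), seeded for reproducibility.
    """
    keep = stats_.beta_gx != 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} variant(s) with beta_GX = 0")
    if not keep.any():
        raise ValueError("all variants have beta_GX = 0")
    bx, sx = stats_.beta_gx[keep], stats_.se_gx[keep]
    by, sy = stats_.beta_gy[keep], stats_.se_gy[keep]
    if keep.sum() < 3:
        raise ValueError("weighted median needs >= 3 usable variants")
    ratios = by / bx
    w = bx**2 / sy**2
    theta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0
        boots[b] = _weighted_median(by_b[ok] / bx_b[ok], bx_b[ok] ** 2 / sy[ok] ** 2)
    se = float(boots.std(ddof=1))
    return MREstimate(
        theta=theta,
        se=se,
        scale=scale,
        method="weighted_median",
        extras={"n_boot": n_boot, "n_variants": int(keep.sum())},
    )


def contamination_mixture(
    stats_: SummaryStats,
    psi: float | None = None,
    scale: str = "logOR",
    n_grid: int = 501,
    grid_extension: float = 0.25,
) -> MREstimate:
    """Contamination-mixture estimate by profile likelihood.

    Each variant's ratio t_j = beta_GY_j/beta_GX_j is modelled as valid
    ~ N(theta, se_j^2) or invalid ~ N(0, psi^2 + se_j^2); at each candidate
    theta on a grid every variant takes its better classification and the
    profile log-likelihood is maximised. The 95% set is
    {theta : 2*(max ll - ll(theta)) < 3.84}, which may be a union of
    intervals: the hull is reported as ci95 with the modes in extras.
    ``psi`` defaults to 1.5x the SD of the ratio estimates.
    """
    J = len(stats_)
    if J < 3:
        raise ValueError("contamination mixture needs >= 3 variants")
    keep = stats_.beta_gx != 0
    bx, by, sy = stats_.beta_gx[keep], stats_.beta_gy[keep], stats_.se_gy[keep]
    ratios = by / bx
    ses = sy / np.abs(bx)
    # a near-null beta_GX makes the ratio arbitrarily wild with an equally wild
    # se; such variants carry no information about theta and would stretch the
    # grid (and the default psi) uselessly, so they are ignored for both
    informative = ses <= 10 * np.median(ses)
    if informative.sum() < 3:
        informative = np.ones_like(informative)
    t_inf = ratios[informative]
    if psi is None:
        psi = 1.5 * float(np.std(t_inf, ddof=1))
        if psi == 0:
            psi = 1.5 * float(np.median(ses))
    if psi <= 0:
        raise ValueError("psi must be positive")
    lo, hi = t_inf.min(), t_inf.max()
    width = hi - lo
    if width == 0:
        lo, hi = lo - 2 * ses.max(), hi + 2 * ses.max()
        width = hi - lo
    if width == 0:
        raise ValueError("degenerate grid: zero width")
    grid = np.linspace(lo - grid_extension * width, hi + grid_extension * width, n_grid)

    sd_inv = np.sqrt(psi**2 + ses**2)
    ll_valid = stats.norm.logpdf(ratios[None, :], loc=grid[:, None], scale=ses[None, :])
    ll_invalid = stats.norm.logpdf(ratios, loc=0.0, scale=sd_inv)[None, :]
    profile = np.maximum(ll_valid, ll_invalid).sum(axis=1)

    best = int(profile.argmax())
    theta = float(grid[best])
    inside = 2 * (profile[best] - profile) < stats.chi2.ppf(0.95, 1)
    # contiguous runs of grid points inside the likelihood-ratio set
    idx = np.flatnonzero(inside)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    modes = [(float(grid[r[0]]), float(grid[r[-1]])) for r in runs]
    ci = (modes[0][0], modes[-1][1])
    se = (ci[1] - ci[0]) / (2 * 1.96)
    valid_at_best = ll_valid[best] >= ll_invalid[0]
    return MREstimate(
        theta=theta,
        se=float(se),
        scale=scale,
        method="conmix",
        ci95=ci,
        extras={
            "conmix_modes": modes,
            "psi": float(psi),
            "n_valid": int(valid_at_best.sum()),
            "valid_variants": [v for v, ok in zip(np.array(stats_.variant_id)[keep], valid_at_best) if ok],
            "n_grid": n_grid,
        },
    )


def _fit_scores_block(scores: pd.DataFrame, outcome, covariates, model: str, **surv):
    """Coefficients and covariance of all score columns in a joint outcome fit."""
    import statsmodels.api as sm

    X = pd.concat([scores.reset_index(drop=True)], axis=1)
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    names = list(scores.columns)
    if model == "cox":
        from lifelines import CoxPHFitter

        df = X.copy()
        df["exit_age"] = np.asarray(outcome, float)
        df["event"] = np.asarray(surv["event"]).astype(int)
        kwargs = {}
        if surv.get("entry_age") is not None:
            df["entry_age"] = np.asarray(surv["entry_age"], float)
            kwargs["entry_col"] = "entry_age"
        cph = CoxPHFitter()
        cph.fit(df, duration_col="exit_age", event_col="event", **kwargs)
        coefs = cph.params_[names].to_numpy()
        cov = cph.variance_matrix_.loc[names, names].to_numpy()
        return coefs, cov, "logHR"
    Xc = sm.add_constant(X)
    if model == "logistic":
        fit = sm.Logit(np.asarray(outcome, float), Xc).fit(disp=0)
        scale = "logOR"
    elif model == "linear":
        fit = sm.OLS(np.asarray(outcome, float), Xc).fit()
        scale = "identity"
    else:
        raise ValueError(f"unknown model {model!r}")
    coefs = fit.params[names].to_numpy()
    cov = fit.cov_params().loc[names, names].to_numpy()
    return coefs, cov, scale


def mvmr_grs(
    scores: pd.DataFrame,
    exposures: pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    model: str = "logistic",
    entry_age=None,
    event=None,
) -> MVMRResult:
    """Multivariable MR with one genetic risk score per exposure.

    Stage 1 regresses each exposure on all scores (+ covariates) giving the
    score-exposure coefficient matrix B; stage 2 fits the outcome on all
    scores (+ covariates) giving coefficients c with covariance V. Direct
    effects solve B^T theta = c, with delta-method covariance
    (B^T)^-1 V B^-1 treating B as fixed (first-order; appropriate when
    conditional F is large). Scores with zero variance are dropped together
    with their exposure (they cannot identify it).
    """
    import statsmodels.api as sm

    scores = scores.copy()
    exposures = exposures.copy()
    if list(scores.columns) != list(exposures.columns):
        scores.columns = exposures.columns
    degenerate = [c for c in scores.columns if np.ptp(scores[c].to_numpy(float)) == 0]
    if degenerate:
        warnings.warn(f"dropping unidentified exposures (constant score): {degenerate}")
        scores = scores.drop(columns=degenerate)
        exposures = exposures.drop(columns=degenerate)
    names = list(exposures.columns)
    k = len(names)
    if k == 0:
        raise ValueError("no usable exposures")

    Xc = sm.add_constant(
        pd.concat([scores.reset_index(drop=True)], axis=1)
        if covariates is None
        else pd.concat([scores.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    )
    B = np.empty((k, k))  # rows: exposures, cols: scores
    for i, e in enumerate(names):
        fit = sm.OLS(exposures[e].to_numpy(float), Xc).fit()
        B[i] = fit.params[list(scores.columns)].to_numpy()

    if abs(np.linalg.det(B)) < 1e-12 * max(1.0, np.abs(B).max() ** k):
        raise ValueError("exposures not separately identified: score-exposure matrix singular")

    c, V, scale = _fit_scores_block(
        scores, outcome, covariates, model, entry_age=entry_age, event=event
    )
    Bt_inv = np.linalg.inv(B.T)
    theta = Bt_inv @ c
    cov = Bt_inv @ V @ Bt_inv.T
    se = np.sqrt(np.diag(cov))
    ci = [(t - 1.96 * s, t + 1.96 * s) for t, s in zip(theta, se)]
    cf = conditional_f(scores, exposures, covariates) if k >= 2 else np.array([np.nan])
    note = (
        f"each exposure adjusted for genetically predicted {', '.join(names)}"
        if k >= 2
        else "single exposure (univariable reduction)"
    )
    return MVMRResult(
        exposures=names,
        theta=theta,
        se=se,
        ci95=ci,
        conditional_f=cf,
        scale=scale,
        note=note,
    )


def conditional_f(
    scores: pd.DataFrame, exposures: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> np.ndarray:
    """Sanderson-Windmeijer-style conditional instrument strength.

    For each exposure: partial out the other exposures' genetically
    predicted components (stage-1 fitted values), then compute the F
    statistic of the instrument block for the residual, with numerator
    degrees of freedom reduced by the number of other exposures.
    """
    if exposures.shape[1] < 2:
        raise ValueError("conditional F needs >= 2 exposures; use score_strength")
    n = len(exposures)
    S = scores.to_numpy(float)
    C = covariates.to_numpy(float) if covariates is not None and len(covariates.columns) else np.empty((n, 0))
    const = np.ones((n, 1))
    base = np.column_stack([const, C])
    full = np.column_stack([const, C, S])

    def _resid(y, X):
        return y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

    # stage-1 predicted exposures
    preds = {}
    for e in exposures.columns:
        y = exposures[e].to_numpy(float)
        preds[e] = full @ np.linalg.lstsq(full, y, rcond=None)[0]

    out = np.empty(exposures.shape[1])
    k_inst = S.shape[1]
    n_other = exposures.shape[1] - 1
    q = max(k_inst - n_other, 1)
    for i, e in enumerate(exposures.columns):
        others = np.column_stack([preds[o] for o in exposures.columns if o != e])
        y = exposures[e].to_numpy(float)
        r = _resid(y, np.column_stack([base, others]))
        rss0 = (_resid(r, base) ** 2).sum()
        rss1 = (_resid(r, full) ** 2).sum()
        df_resid = n - full.shape[1] - n_other
        out[i] = ((rss0 - rss1) / q) / (rss1 / df_resid)
    return out


def subgroup_difference_z(est1: MREstimate, est2: MREstimate) -> tuple:
    """Two-sided z test for a difference between two subgroup estimates.

    z = (theta1 - theta2) / sqrt(se1^2 + se2^2); p = 2*Phi(-|z|). Estimates
    must be on the same scale.
    """
    if est1.scale != est2.scale:
        raise ValueError(f"scale mismatch: {est1.scale} vs {est2.scale}")
    denom = np.sqrt(est1.se**2 + est2.se**2)
    if denom == 0:
        return (0.0, 1.0) if est1.theta == est2.theta else (np.inf, 0.0)
    z = (est1.theta - est2.theta) / denom
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class ExpEstimate:
    point: float
    ci95: tuple
    scale: str  # OR | HR
    per_sd: float


def exponentiate(est: MREstimate, sd_units: float = 1.0) -> ExpEstimate:
    """OR/HR with CI per ``sd_units`` of the exposure.

    Rescales theta to per-SD units then exponentiates point and CI; log of
    the result recovers the input to machine precision.
    """
    if est.scale == "logOR":
        out_scale = "OR"
    elif est.scale == "logHR":
        out_scale = "HR"
    else:
        raise ValueError("exponentiate requires a logOR or logHR scale estimate")
    lo, hi = est.ci95
    return ExpEstimate(
        point=float(np.exp(est.theta * sd_units)),
        ci95=(float(np.exp(lo * sd_units)), float(np.exp(hi * sd_units))),
        scale=out_scale,
        per_sd=sd_units,
    )


def estimate_from_ci(point: float, lo: float, hi: float, scale: str = "logOR") -> MREstimate:
    """Rebuild a log-scale estimate from a printed OR/HR with its 95% CI.

    se = (ln hi - ln lo) / (2 * 1.96) — the standard reconstruction used to
    compare published subgroup estimates.
    """
    theta = np.log(point)
    se = (np.log(hi) - np.log(lo)) / (2 * 1.96)
    return MREstimate(
        theta=float(theta),
        se=float(se),
        scale=scale,
        method="ratio",
        ci95=(float(np.log(lo)), float(np.log(hi))),
    )
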