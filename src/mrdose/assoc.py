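"""Covariate-adjusted gene-exposure and gene-outcome association engines.

Four fitters share a common result type:

* :func:`linear_assoc` — OLS for quantitative traits;
* :func:`logistic_assoc` — maximum-likelihood logistic regression for binary
  disease status (prevalent + incident combined), scale ``logOR``;
* :func:`cox_assoc` — Cox partial likelihood on the attained-age timescale
  with delayed entry (risk set at age t = {entry_age < t <= exit_age}),
  Efron tie handling, scale ``logHR``;
* :func:`cause_specific_cox` — the same after recoding competing causes of
  death as censorings at their event age.

Two named adjustment presets mirror a standard epidemiological design:
``cad_set`` (baseline age, age^2, sex, age x sex, age^2 x sex, 20 PCs) for
lipid traits and disease, and ``mortality_set`` (birth year terms in place of
age, since attained age is the timescale) for mortality outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssocResult",
    "adjustment_matrix",
    "linear_assoc",
    "logistic_assoc",
    "cox_assoc",
    "cause_specific_cox",
    "variant_associations",
]

#: Newton-Raphson style fitters: iteration cap and relative loglik tolerance
MAX_ITER = 200
LL_TOL = 1e-8


@dataclass
class AssocResult:
    beta: float
    se: float
    p: float
    n: int
    scale: str  # identity | logOR | logHR
    adjustment_set: str = "none"
    extras: dict = field(default_factory=dict)

    @property
    def ci95(self) -> tuple:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return 2 * stats.norm.sf(abs(beta / se))


def adjustment_matrix(table: pd.DataFrame, preset: str) -> pd.DataFrame:
    """Build the named adjustment design (without intercept) from a cohort table.

    ``cad_set``: age, age^2, sex, age*sex, age^2*sex, pc1..pc20 (baseline-age
    adjustment for lipid/disease models). ``mortality_set``: the same
    structure on birth year (attained-age timescale models). ``none``: empty.
    Age/birth-year are centred before powers for numerical conditioning; the
    score coefficient is invariant to this reparametrization.
    """
    if preset == "none":
        return pd.DataFrame(index=table.index)
    if preset == "cad_set":
        base = table["age_at_recruitment"]
    elif preset == "mortality_set":
        base = table["birth_year"]
    else:
        raise ValueError(f"unknown adjustment preset {preset!r}")
    t = base - base.mean()
    sex = table["sex"].astype(float)
    out = pd.DataFrame(
        {
            "t": t,
            "t2": t**2,
            "sex": sex,
            "t_sex": t * sex,
            "t2_sex": t**2 * sex,
        },
        index=table.index,
    )
    for c in table.columns:
        if c.startswith("pc"):
            out[c] = table[c]
    # inside a subgroup some terms degenerate (sex is constant within a
    # sex-specific fit; t_sex duplicates t when sex == 1): keep a maximal
    # linearly independent subset so the design stays identifiable
    A = np.column_stack([np.ones(len(out))])
    keep = []
    for c in out.columns:
        col = out[c].to_numpy(float)
        cand = np.column_stack([A, col])
        if np.linalg.matrix_rank(cand) > A.shape[1]:
            keep.append(c)
            A = cand
    return out[keep]


def _design(score, covariates, add_const=True):
    score = np.asarray(score, float)
    n = len(score)
    cols = {"score": score}
    if covariates is not None:
        for c in covariates.columns:
            cols[c] = covariates[c].to_numpy(float)
    X = pd.DataFrame(cols)
    if add_const:
        X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame):
    A = X.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify offending columns by incremental rank
        bad, cur = [], np.empty((A.shape[0], 0))
        for j, name in enumerate(X.columns):
            cand = np.column_stack([cur, A[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def linear_assoc(
    outcome, score, covariates: pd.DataFrame | None = None, adjustment_set: str = "custom"
) -> AssocResult:
    """OLS association of a quantitative outcome with the score."""
    import statsmodels.api as sm

    y = np.asarray(outcome, float)
    X = _design(score, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    beta, se = fit.params["score"], fit.bse["score"]
    return AssocResult(
        beta=float(beta),
        se=float(se),
        p=_normal_p(beta, se),
        n=len(y),
        scale="identity",
        adjustment_set=adjustment_set,
    )


def logistic_assoc(
    outcome, score, covariates: pd.DataFrame | None = None, adjustment_set: str = "custom"
) -> AssocResult:
    """Maximum-likelihood logistic association; beta is a log odds ratio."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(outcome, float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must contain both classes")
    X = _design(score, covariates)
    _check_rank(X)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER, tol=LL_TOL)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValueError("separation detected") from err
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"logistic fit did not converge in {fit.mle_retvals.get('iterations')} iterations"
        )
    beta, se = fit.params["score"], fit.bse["score"]
    if not np.isfinite(se) or se > 1e3:
        raise ValueError("separation detected")
    return AssocResult(
        beta=float(beta),
        se=float(se),
        p=_normal_p(beta, se),
        n=len(y),
        scale="logOR",
        adjustment_set=adjustment_set,
        extras={"converged": True, "max_iter": MAX_ITER, "ll_tol": LL_TOL},
    )


def cox_assoc(
    exit_age,
    event,
    score,
    covariates: pd.DataFrame | None = None,
    entry_age=None,
    adjustment_set: str = "custom",
) -> AssocResult:
    """Cox partial-likelihood association on the attained-age timescale.

    ``entry_age`` enables delayed entry (left truncation at recruitment);
    ties are handled by the Efron approximation. Shifting all entry/exit
    ages by a constant that preserves risk-set membership leaves the
    estimate unchanged (partial-likelihood invariance).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    event = np.asarray(event).astype(bool)
    if event.sum() == 0:
        raise ValueError("zero events")
    X = _design(score, covariates, add_const=False)
    for c in X.columns:
        if np.ptp(X[c].to_numpy()) == 0:
            raise ValueError(f"non-identifiable: covariate {c!r} is constant")
    df = X.copy()
    df["exit_age"] = np.asarray(exit_age, float)
    df["event"] = event.astype(int)
    kwargs = {}
    if entry_age is not None:
        df["entry_age"] = np.asarray(entry_age, float)
        if (df["entry_age"] >= df["exit_age"]).any():
            raise ValueError("entry_age must precede exit_age")
        kwargs["entry_col"] = "entry_age"
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="exit_age", event_col="event", **kwargs)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
        raise ValueError(f"non-identifiable: {err}") from err
    beta = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    return AssocResult(
        beta=beta,
        se=se,
        p=_normal_p(beta, se),
        n=len(df),
        scale="logHR",
        adjustment_set=adjustment_set,
        extras={"n_events": int(event.sum()), "ties": "efron"},
    )


def cause_specific_cox(
    exit_age,
    event_cause,
    cause: str,
    score,
    covariates: pd.DataFrame | None = None,
    entry_age=None,
    adjustment_set: str = "custom",
) -> AssocResult:
    """Cause-specific hazard: events of other causes become censorings.

    ``event_cause`` holds per-individual labels ('none' for administratively
    censored); the model is identical to :func:`cox_assoc` applied to the
    recoded record.
    """
    labels = np.asarray(event_cause).astype(str)
    if cause not in {"cvd", "cancer", "other"}:
        raise ValueError(f"unknown cause {cause!r}")
    event = labels == cause
    if event.sum() == 0:
        raise ValueError(f"no events of cause {cause!r}")
    res = cox_assoc(
        exit_age, event, score, covariates, entry_age=entry_age, adjustment_set=adjustment_set
    )
    res.extras["cause"] = cause
    return res


def variant_associations(
    dosages: pd.DataFrame,
    outcome,
    model: str = "linear",
    covariates: pd.DataFrame | None = None,
    entry_age=None,
    event=None,
) -> pd.DataFrame:
    """Per-variant association scan (one fit per dosage column).

    Returns a DataFrame indexed by variant id with columns beta, se — the
    raw material of summary-statistic MR estimators. ``model`` is 'linear',
    'logistic' or 'cox' (for which ``outcome`` is exit age and ``event`` the
    indicator).
    """
    rows = {}
    for v in dosages.columns:
        d = dosages[v]
        if model == "linear":
            r = linear_assoc(outcome, d, covariates)
        elif model == "logistic":
            r = logistic_assoc(outcome, d, covariates)
        elif model == "cox":
            r = cox_assoc(outcome, event, d, covariates, entry_age=entry_age)
        else:
            raise ValueError(f"unknown model {model!r}")
        rows[v] = {"beta": r.beta, "se": r.se}
    return pd.DataFrame.from_dict(rows, orient="index")
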