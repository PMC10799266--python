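"""Genetic risk scores, instrument diagnostics and exposure normalization.

A genetic risk score (GRS) is the per-individual weighted sum of
effect-allele dosages, with weights taken from an external GWAS (never
re-estimated in the analysis cohort). Instrument strength is summarised by
the incremental R^2 of the score in a covariate-adjusted regression of the
exposure and the corresponding F statistic; F > 10 is the conventional
threshold below which weak-instrument bias is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantWeight",
    "ScoreDiagnostics",
    "build_grs",
    "score_strength",
    "prune_variants",
    "confounder_check",
    "inverse_rank_normalize",
    "weights_from_table",
]

#: flag rule for GRS-confounder associations carried into sensitivity models
CONFOUNDER_P_THRESHOLD = 0.01
WEAK_INSTRUMENT_F = 10.0


@dataclass(frozen=True)
class VariantWeight:
    variant_id: str
    effect_allele: str
    weight: float
    source: str = ""

    def __post_init__(self):
        if not np.isfinite(self.weight):
            raise ValueError(f"non-finite weight for {self.variant_id}")


@dataclass
class ScoreDiagnostics:
    """Instrument-strength summary for a single GRS."""

    r2: float
    f_stat: float
    n: int
    confounder_assocs: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def weak(self) -> bool:
        return self.f_stat <= WEAK_INSTRUMENT_F


def weights_from_table(df: pd.DataFrame, source: str = "") -> list[VariantWeight]:
    """Build VariantWeights from a GWAS-layout table (variant_id, effect_allele, beta)."""
    dup = df["variant_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate variant ids: {sorted(df.loc[dup, 'variant_id'])}")
    return [
        VariantWeight(r.variant_id, r.effect_allele, float(r.beta), source)
        for r in df.itertuples()
    ]


def build_grs(
    dosages: pd.DataFrame,
    weights: list[VariantWeight],
    dosage_alleles: pd.DataFrame | None = None,
) -> pd.Series:
    """Weighted allele score: score_i = sum_j w_j * dosage_ij.

    ``dosage_alleles``, when given, is indexed by variant id with columns
    ``counted_allele`` / ``other_allele`` describing which allele the dosage
    column counts. A weight whose effect allele is the *other* allele
    contributes ``w * (2 - dosage)`` (allele flip); any other mismatch is an
    error. Without allele information the dosages are assumed aligned.
    """
    missing = [w.variant_id for w in weights if w.variant_id not in dosages.columns]
    if missing:
        raise KeyError(f"variants missing from dosage matrix: {missing}")
    score = np.zeros(len(dosages))
    for w in weights:
        d = dosages[w.variant_id].to_numpy(float)
        if dosage_alleles is not None and w.variant_id in dosage_alleles.index:
            counted = dosage_alleles.loc[w.variant_id, "counted_allele"]
            other = dosage_alleles.loc[w.variant_id, "other_allele"]
            if w.effect_allele == counted:
                pass
            elif w.effect_allele == other:
                d = 2.0 - d
            else:
                raise ValueError(
                    f"allele mismatch for {w.variant_id}: effect allele "
                    f"{w.effect_allele!r} is neither {counted!r} nor {other!r}"
                )
        score += w.weight * d
    return pd.Series(score, index=dosages.index, name="grs")


def _incremental_r2(y, score, covariates):
    """R^2 gained by adding the score to a linear regression of y on covariates."""
    y = np.asarray(y, float)
    n = len(y)
    if covariates is None or np.size(covariates) == 0:
        X0 = np.ones((n, 1))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        X0 = np.column_stack([np.ones(n), C])
    X1 = np.column_stack([X0, np.asarray(score, float)])
    tss = ((y - y.mean()) ** 2).sum()
    rss0 = ((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2).sum()
    rss1 = ((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2).sum()
    return max((rss0 - rss1) / tss, 0.0)


def score_strength(
    score, exposure, covariates: pd.DataFrame | None = None, marginal: bool = False
) -> ScoreDiagnostics:
    """Proportion of exposure variance explained by the score and its F statistic.

    ``r2`` is the incremental (covariate-adjusted) R^2 by default, or the
    marginal R^2 of the score alone with ``marginal=True``. The F statistic
    uses the univariate form F = (n - 2) R^2 / (1 - R^2).
    """
    score = np.asarray(score, float)
    exposure = np.asarray(exposure, float)
    n = len(score)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if score.std() == 0:
        raise ValueError("degenerate instrument: score is constant")
    covs = None
    if not marginal and covariates is not None and len(covariates.columns):
        covs = covariates.to_numpy(float)
    r2 = _incremental_r2(exposure, score, covs)
    r2 = min(r2, 1.0 - 1e-12)
    f = (n - 2) * r2 / (1.0 - r2)
    return ScoreDiagnostics(r2=r2, f_stat=f, n=n)


def prune_variants(
    pvalues: pd.Series, r2_matrix: pd.DataFrame, r2_threshold: float = 0.001
) -> list[str]:
    """Greedy LD pruning: keep the most significant variant of each correlated set.

    Candidates are visited in ascending p-value (ties broken by variant id);
    a variant is kept iff its r^2 with every already-kept variant is below
    ``r2_threshold``. Idempotent: pruning the kept set changes nothing.
    """
    ids = list(pvalues.index)
    R = r2_matrix.loc[ids, ids].to_numpy(float)
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("r2 matrix is not symmetric")
    order = sorted(ids, key=lambda v: (pvalues[v], v))
    kept: list[str] = []
    pos = {v: i for i, v in enumerate(ids)}
    for v in order:
        if all(R[pos[v], pos[k]] < r2_threshold for k in kept):
            kept.append(v)
    return [v for v in ids if v in set(kept)]


def confounder_check(score, covariate_table: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate association of a standardized GRS with candidate confounders.

    Logistic regression for binary covariates, linear otherwise; covariates
    with p below 0.01 are flagged (the rule used to decide which confounders
    enter multivariable sensitivity models). Constant covariates are skipped
    with a warning.
    """
    import statsmodels.api as sm

    score = np.asarray(score, float)
    z = (score - score.mean()) / score.std()
    rows = []
    for name in covariate_table.columns:
        y = covariate_table[name].to_numpy(float)
        if np.ptp(y) == 0:
            warnings.warn(f"covariate {name!r} is constant; skipped")
            continue
        X = sm.add_constant(z)
        vals = np.unique(y)
        if len(vals) == 2:
            yy = (y == vals.max()).astype(float)
            fit = sm.Logit(yy, X).fit(disp=0)
        else:
            fit = sm.OLS(y, X).fit()
        est, se = fit.params[1], fit.bse[1]
        p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else 0.0
        rows.append(
            {
                "covariate": name,
                "estimate": est,
                "se": se,
                "p": p,
                "flagged": p < CONFOUNDER_P_THRESHOLD,
            }
        )
    return pd.DataFrame(rows, columns=["covariate", "estimate", "se", "p", "flagged"])


def inverse_rank_normalize(values) -> np.ndarray:
    """Blom inverse rank-normal transform: rank r -> Phi^-1((r - 3/8)/(n + 1/4)).

    Ties get average ranks. Preserves order, commutes with any strictly
    increasing transform of the input, and yields mean ~0, SD ~1.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0:
        raise ValueError("no variation: all values equal")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))
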