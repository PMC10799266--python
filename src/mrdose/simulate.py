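"""Synthetic cohort generator for Mendelian randomization analyses.

Generates individual-level cohorts with the structure an MR analysis of a
quantitative exposure (a lipid trait, say) against disease and mortality
outcomes assumes:

* ``m`` independent biallelic variants with small per-allele effects that
  jointly explain a target fraction (``target_r2``, default 12%) of the
  exposure variance — the instrument set;
* a single unmeasured confounder ``U ~ N(0, 1)`` acting on the exposure and
  on every outcome, so that naive regression is biased while a valid
  instrumental-variable analysis is consistent;
* a binary disease outcome via a logistic link, with prevalence around 7%;
* three competing causes of death (cvd, cancer, other) with cause-specific
  Weibull hazards on the attained-age timescale, delayed entry at the
  recruitment age, and administrative censoring at a fixed age;
* an optional pre-recruitment selection model (inclusion probability
  decreasing in exposure) to emulate survivorship into the cohort.

The causal effect of the exposure on each outcome is a configurable curve
``f`` on the log-odds / log-hazard scale; :func:`true_curve` exposes it on a
grid (centred at the grid median) as the oracle for recovery tests of the
nonlinear MR machinery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CausalCurve",
    "SelectionModel",
    "SimConfig",
    "Cohort",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_outcomes",
    "simulate_cohort",
    "simulate_mvmr_cohort",
    "true_curve",
    "write_cohort",
    "read_cohort",
]

CAUSES = ("cvd", "cancer", "other")

#: calendar year anchoring birth_year = RECRUITMENT_YEAR - age_at_recruitment
RECRUITMENT_YEAR = 2008.0

_CURVE_ARITY = {"linear": 1, "quadratic": 2, "threshold": 2, "jshape": 3}


@dataclass(frozen=True)
class CausalCurve:
    """Causal exposure effect f(x) on the log-odds / log-hazard scale.

    Shapes (c = coefficients):
      linear     f(x) = c0*x
      quadratic  f(x) = c0*x + c1*x^2
      threshold  f(x) = c0*max(x - c1, 0)
      jshape     f(x) = c0*(x - c2) + c1*(x - c2)^2
    """

    shape: str = "linear"
    coefficients: tuple = (0.5,)

    def __post_init__(self):
        if self.shape not in _CURVE_ARITY:
            raise ValueError(f"unknown curve shape {self.shape!r}")
        if len(self.coefficients) != _CURVE_ARITY[self.shape]:
            raise ValueError(
                f"{self.shape} curve takes {_CURVE_ARITY[self.shape]} "
                f"coefficients, got {len(self.coefficients)}"
            )
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.shape == "linear":
            return c[0] * x
        if self.shape == "quadratic":
            return c[0] * x + c[1] * x**2
        if self.shape == "threshold":
            return c[0] * np.maximum(x - c[1], 0.0)
        # jshape
        return c[0] * (x - c[2]) + c[1] * (x - c[2]) ** 2


@dataclass(frozen=True)
class SelectionModel:
    """Pre-recruitment inclusion: P(include) = expit(intercept - slope*exposure)."""

    intercept: float = 2.0
    slope: float = 0.5


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults emulate a mid-life population-biobank analysis sample: recruitment ages
    40-69, a genetic score explaining ~12% of exposure variance, disease
    prevalence ~7%, and ~7% deaths split across three competing causes
    (roughly 20/51/27% cvd/cancer/other) by administrative censoring.
    """

    n_individuals: int = 20_000
    n_variants: int = 150
    maf_range: tuple = (0.05, 0.45)
    variant_effect_sd: float = 1.0
    target_r2: float = 0.12
    confounder_effect_exposure: float = 0.5
    confounder_effect_outcome: float = 0.4
    causal_curve: CausalCurve = field(default_factory=CausalCurve)
    disease_intercept: float = -2.86
    recruitment_age_range: tuple = (40.0, 69.0)
    #: per-cause Weibull (shape, rate); hazard h0(a) = shape*rate*(rate*a)^(shape-1)
    baseline_hazard: dict = field(
        default_factory=lambda: {
            "cvd": (5.0, 0.00513),
            "cancer": (5.0, 0.0065),
            "other": (5.0, 0.00567),
        }
    )
    #: per-cause multiplier applied to the causal curve on the log-hazard scale
    cause_effect_scale: dict = field(
        default_factory=lambda: {"cvd": 1.0, "cancer": 0.0, "other": 0.25}
    )
    admin_censor_age: float = 81.5
    selection: SelectionModel | None = None
    #: residual exposure noise SD; None derives it so total exposure variance is 1
    exposure_noise_sd: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_variants == 0:
            raise ValueError("no instruments: n_variants must be positive")
        if self.n_variants < 0:
            raise ValueError("n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.target_r2 < 1.0):
            raise ValueError("target_r2 must be in (0, 1)")
        if self.variant_effect_sd <= 0:
            raise ValueError("variant_effect_sd must be positive")
        if set(self.baseline_hazard) != set(CAUSES):
            raise ValueError(f"baseline_hazard must have keys {CAUSES}")
        for cause, (shape, rate) in self.baseline_hazard.items():
            if shape <= 0 or rate < 0:
                raise ValueError(f"invalid Weibull parameters for cause {cause!r}")
        a0, a1 = self.recruitment_age_range
        if not (0 < a0 < a1 < self.admin_censor_age):
            raise ValueError("recruitment_age_range must precede admin_censor_age")


@dataclass
class Cohort:
    """A simulated analysis sample.

    ``table`` holds one row per individual (exposure, confounder, sex,
    ages, pcs, disease and survival record); ``dosages`` the n-by-m matrix of
    effect-allele counts in [0, 2]. ``true_weights`` are the per-variant
    exposure effects actually used — oracle material for tests, never an
    input to the estimators.
    """

    table: pd.DataFrame
    dosages: pd.DataFrame
    true_weights: pd.Series
    config: SimConfig

    @property
    def n(self) -> int:
        return len(self.table)

    def to_table(self) -> pd.DataFrame:
        """Single flat table: phenotype columns then g-prefixed dosage columns."""
        dos = self.dosages.add_prefix("g_")
        return pd.concat([self.table.reset_index(drop=True), dos.reset_index(drop=True)], axis=1)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genotypes(config: SimConfig, rng=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw independent biallelic dosages.

    Column j is Binomial(2, MAF_j) — two independent allele draws — with
    MAF_j sampled uniformly from ``config.maf_range``. Returns the dosage
    DataFrame (columns ``v0001``...) and the drawn MAF vector.
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    n, m = config.n_individuals, config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    cols = [f"v{j + 1:04d}" for j in range(m)]
    return pd.DataFrame(dosages, columns=cols), mafs


def simulate_exposure(
    dosages: pd.DataFrame, config: SimConfig, rng=None, confounder=None
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Exposure = G·w + gamma_x·U + eps, with w rescaled to hit target_r2.

    Raw per-variant effects are drawn N(0, variant_effect_sd) and rescaled so
    the genetic component's sample variance equals ``target_r2`` (total
    exposure variance is ~1 by default, so target_r2 is the variance
    fraction explained by the true score). Returns (exposure, confounder,
    true_weights).
    """
    if not (0.0 < config.target_r2 < 1.0):
        raise ValueError("target_r2 must be in (0, 1)")
    rng = _rng(config.seed if rng is None else rng)
    G = dosages.to_numpy(dtype=float)
    n, m = G.shape
    w_raw = rng.normal(0.0, config.variant_effect_sd, size=m)
    score_raw = G @ w_raw
    v = score_raw.var()
    if v <= 0:
        raise ValueError("degenerate genotypes: true score has zero variance")
    w = w_raw * np.sqrt(config.target_r2 / v)
    genetic = G @ w

    U = rng.standard_normal(n) if confounder is None else np.asarray(confounder, float)
    gx = config.confounder_effect_exposure
    if config.exposure_noise_sd is None:
        resid_var = 1.0 - config.target_r2 - gx**2
        if resid_var < 0:
            raise ValueError(
                "target_r2 + confounder_effect_exposure^2 exceeds 1; "
                "set exposure_noise_sd explicitly"
            )
        noise_sd = np.sqrt(resid_var)
    else:
        noise_sd = float(config.exposure_noise_sd)
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    exposure = genetic + gx * U + eps
    return exposure, U, pd.Series(w, index=dosages.columns, name="true_weight")


def _weibull_event_age(rng, shape, rate, entry_age, log_rr):
    """Event age from a Weibull cause-specific hazard with delayed entry.

    Solves (rate*T)^shape = (rate*a0)^shape + E / exp(log_rr), E ~ Exp(1),
    i.e. inverse-transform sampling of the conditional survival from entry.
    """
    if rate == 0:
        return np.full(len(entry_age), np.inf)
    E = rng.exponential(size=len(entry_age))
    H0 = (rate * entry_age) ** shape
    return ((H0 + E * np.exp(-log_rr)) ** (1.0 / shape)) / rate


def simulate_outcomes(
    exposure, confounder, covariates: pd.DataFrame, config: SimConfig, rng=None
) -> pd.DataFrame:
    """Disease status and the competing-risks survival record.

    Disease: P = expit(disease_intercept + f(x) - f(median x) + gamma_y*U).
    Deaths: for each cause, an event age from a proportional-hazards Weibull
    model on the attained-age timescale starting at the recruitment age
    (delayed entry); the earliest cause wins; administrative censoring at
    ``admin_censor_age``. Centring f at the median exposure makes the
    intercept/rates control prevalence at the cohort median.
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    x = np.asarray(exposure, float)
    U = np.asarray(confounder, float)
    n = len(x)
    entry_age = np.asarray(covariates["age_at_recruitment"], float)

    f = config.causal_curve(x) - config.causal_curve(np.median(x))
    gy = config.confounder_effect_outcome

    from scipy.special import expit

    p_disease = expit(config.disease_intercept + f + gy * U)
    disease = rng.binomial(1, p_disease).astype(int)

    if all(rate == 0 for _, rate in config.baseline_hazard.values()):
        raise ValueError("no events possible: all baseline hazard rates are zero")

    event_ages = np.full((len(CAUSES), n), np.inf)
    for i, cause in enumerate(CAUSES):
        shape, rate = config.baseline_hazard[cause]
        log_rr = config.cause_effect_scale.get(cause, 0.0) * f + gy * U
        event_ages[i] = _weibull_event_age(rng, shape, rate, entry_age, log_rr)

    first = event_ages.min(axis=0)
    which = event_ages.argmin(axis=0)
    censored = first >= config.admin_censor_age
    exit_age = np.where(censored, config.admin_censor_age, first)
    cause = np.where(censored, "none", np.array(CAUSES)[which])
    # guard the exit > entry invariant against degenerate draws
    exit_age = np.maximum(exit_age, entry_age + 1e-6)

    return pd.DataFrame(
        {
            "disease": disease,
            "entry_age": entry_age,
            "exit_age": exit_age,
            "event_cause": pd.Categorical(cause, categories=("none",) + CAUSES),
        }
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Full cohort draw; bit-reproducible under a fixed ``config.seed``.

    Each stage (genotypes, exposure, covariates, outcomes, selection) uses an
    independent child stream of the seed so stages can be re-run in isolation.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_geno, r_expo, r_cov, r_out, r_sel = (np.random.default_rng(s) for s in ss.spawn(5))

    dosages, _ = simulate_genotypes(config, rng=r_geno)
    exposure, U, weights = simulate_exposure(dosages, config, rng=r_expo)

    n = config.n_individuals
    sex = r_cov.binomial(1, 0.541, size=n)  # 1 = female, matching a ~54% female cohort
    age = r_cov.uniform(*config.recruitment_age_range, size=n)
    pcs = r_cov.standard_normal((n, 20))

    covs = pd.DataFrame({"sex": sex, "age_at_recruitment": age})
    covs["birth_year"] = RECRUITMENT_YEAR - covs["age_at_recruitment"]
    for k in range(20):
        covs[f"pc{k + 1}"] = pcs[:, k]

    outcomes = simulate_outcomes(exposure, U, covs, config, rng=r_out)

    table = pd.concat(
        [pd.DataFrame({"exposure": exposure, "confounder": U}), covs, outcomes], axis=1
    )

    if config.selection is not None:
        from scipy.special import expit

        p_inc = expit(config.selection.intercept - config.selection.slope * exposure)
        keep = r_sel.uniform(size=n) < p_inc
        table = table.loc[keep].reset_index(drop=True)
        dosages = dosages.loc[keep].reset_index(drop=True)

    return Cohort(table=table, dosages=dosages, true_weights=weights, config=config)


def simulate_mvmr_cohort(
    config: SimConfig,
    direct_effects: tuple = (0.5, 0.0),
    weight_correlation: float = 0.5,
    second_r2: float | None = None,
) -> tuple[Cohort, pd.Series, np.ndarray]:
    """Two correlated exposures with distinct direct effects on the outcome.

    The second exposure shares the genotype matrix with the first; its true
    weight vector correlates with the first's (correlation
    ``weight_correlation``), and both load on the same confounder, so the
    exposures are correlated but separately instrumented. The binary outcome
    uses log-odds ``direct_effects[0]*x1 + direct_effects[1]*x2``. Returns
    (cohort-with-x1, true weights of x2, x2 values); the cohort table gains
    an ``exposure2`` column.
    """
    config = dataclasses.replace(config, causal_curve=CausalCurve("linear", (direct_effects[0],)))
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_geno, r_expo, r_cov, r_out, r_x2 = (np.random.default_rng(s) for s in ss.spawn(5))

    dosages, _ = simulate_genotypes(config, rng=r_geno)
    x1, U, w1 = simulate_exposure(dosages, config, rng=r_expo)

    G = dosages.to_numpy(float)
    m = G.shape[1]
    r2_2 = config.target_r2 if second_r2 is None else second_r2
    w2_raw = weight_correlation * w1.to_numpy() + np.sqrt(
        max(1 - weight_correlation**2, 0.0)
    ) * r_x2.normal(0.0, w1.to_numpy().std() + 1e-12, size=m)
    g2 = G @ w2_raw
    w2 = w2_raw * np.sqrt(r2_2 / g2.var())
    gx = config.confounder_effect_exposure
    noise_sd = np.sqrt(max(1.0 - r2_2 - gx**2, 0.0))
    x2 = G @ w2 + gx * U + r_x2.normal(0.0, noise_sd, size=len(x1))

    n = config.n_individuals
    sex = r_cov.binomial(1, 0.541, size=n)
    age = r_cov.uniform(*config.recruitment_age_range, size=n)
    covs = pd.DataFrame({"sex": sex, "age_at_recruitment": age})
    covs["birth_year"] = RECRUITMENT_YEAR - covs["age_at_recruitment"]
    pcs = r_cov.standard_normal((n, 20))
    for k in range(20):
        covs[f"pc{k + 1}"] = pcs[:, k]

    from scipy.special import expit

    eta = (
        config.disease_intercept
        + direct_effects[0] * (x1 - np.median(x1))
        + direct_effects[1] * (x2 - np.median(x2))
        + config.confounder_effect_outcome * U
    )
    disease = r_out.binomial(1, expit(eta)).astype(int)

    table = pd.concat(
        [
            pd.DataFrame(
                {"exposure": x1, "exposure2": x2, "confounder": U, "disease": disease}
            ),
            covs,
        ],
        axis=1,
    )
    cohort = Cohort(
        table=table, dosages=dosages, true_weights=w1, config=config
    )
    return cohort, pd.Series(w2, index=dosages.columns, name="true_weight2"), x2


def true_curve(config: SimConfig, grid) -> np.ndarray:
    """Oracle causal curve on a grid, centred at the grid median.

    Returns f(grid) - f(median(grid)): the log-odds / log-hazard effect
    relative to the median reference, the convention used when exporting
    fitted dose-response curves.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    f = config.causal_curve
    return np.asarray(f(grid) - f(np.median(grid)), dtype=float)


# ---------------------------------------------------------------------------
# cohort I/O: one delimited table + a YAML sidecar carrying the config/seed


def _config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["causal_curve"] = {
        "shape": config.causal_curve.shape,
        "coefficients": list(config.causal_curve.coefficients),
    }
    if config.selection is not None:
        d["selection"] = dataclasses.asdict(config.selection)
    d["maf_range"] = list(config.maf_range)
    d["recruitment_age_range"] = list(config.recruitment_age_range)
    d["baseline_hazard"] = {c: list(v) for c, v in config.baseline_hazard.items()}
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "causal_curve" in d and isinstance(d["causal_curve"], dict):
        cc = d["causal_curve"]
        d["causal_curve"] = CausalCurve(cc["shape"], tuple(cc["coefficients"]))
    if d.get("selection"):
        d["selection"] = SelectionModel(**d["selection"])
    for key in ("maf_range", "recruitment_age_range"):
        if key in d:
            d[key] = tuple(d[key])
    if "baseline_hazard" in d:
        d["baseline_hazard"] = {c: tuple(v) for c, v in d["baseline_hazard"].items()}
    return SimConfig(**d)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as a TSV (dosages g-prefixed) plus a YAML sidecar."""
    path = Path(path)
    cohort.to_table().to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"sim_config": _config_to_dict(cohort.config)}, fh)


def read_cohort(path) -> Cohort:
    path = Path(path)
    flat = pd.read_csv(path, sep="\t")
    dcols = [c for c in flat.columns if c.startswith("g_")]
    dosages = flat[dcols].rename(columns=lambda c: c[2:])
    table = flat.drop(columns=dcols)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    config = SimConfig()
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        config = config_from_dict(meta["sim_config"])
    weights = pd.Series(np.nan, index=dosages.columns, name="true_weight")
    return Cohort(table=table, dosages=dosages, true_weights=weights, config=config)
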