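# Methods

This note records the statistical model behind `mrdose`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions that matter for reproducing results.

## Instrumental-variable model

Mendelian randomization treats genetic variants as instruments for a
quantitative exposure X: a variant (or a weighted score of variants) must be
associated with X (relevance), share no common cause with the outcome
(independence) and affect the outcome only through X (exclusion
restriction). Under these assumptions the ratio of the instrument-outcome
association to the instrument-exposure association estimates the causal
effect even in the presence of unmeasured exposure-outcome confounding.

The genetic risk score (GRS) is the per-individual sum of effect-allele
dosages times external GWAS weights; weights are never re-estimated in the
analysis cohort, which avoids compounding winner's-curse bias. Instrument
strength is reported as the incremental covariate-adjusted R² of the score
and the univariate F statistic F = (n−2)R²/(1−R²); F > 10 is the
conventional threshold for negligible weak-instrument bias. Whether the
variance explained should be marginal or covariate-adjusted is genuinely
ambiguous in common usage; the incremental form is the default and the
marginal form is an option.

## Association engines

* **Linear** (exposures): OLS with the "cad_set" adjustment (baseline age,
  age², sex, age×sex, age²×sex, 20 genetic principal components). Exposures
  are inverse rank-normalized (Blom offset 3/8, average ranks for ties) in
  the linear analysis so that effects are per SD and comparable across
  traits.
* **Logistic** (disease): combined prevalent + incident case status is a
  binary outcome, so logistic regression (not survival analysis) is the
  model; scale log-OR.
* **Cox** (mortality): partial likelihood on the **attained-age timescale**
  with delayed entry at the recruitment age — the risk set at age t contains
  individuals with entry_age < t ≤ exit_age. Because age is the timescale,
  the adjustment set ("mortality_set") replaces baseline age with birth
  year (same polynomial/interaction structure). Ties are handled by the
  Efron approximation: attained-age data tie frequently and Efron is
  accurate and standard (lifelines' default). Convergence: relative
  log-likelihood tolerance 1e-8, iteration cap 200, recorded in result
  metadata.
* **Cause-specific Cox**: identical after recoding events of other causes
  as censorings at their event age. Fine-Gray subdistribution hazards are
  deliberately out of scope — the target is the cause-specific hazard.

Inside subgroup fits some adjustment terms degenerate (sex is constant
within a sex stratum; age×sex duplicates age when sex ≡ 1); the design
builder keeps a maximal linearly independent subset so fits remain
identifiable without user intervention.

## Univariable estimators

* **Ratio**: θ = β_GY/β_GX, se = se_GY/|β_GX| (first-order delta method —
  justified because all intended uses have F ≫ 10; the second-order
  correction term is quadratic in se_GX/β_GX).
* **IVW**: zero-intercept weighted regression of β_GY on β_GX, weights
  1/se_GY²; multiplicative random-effects inflation of the SE by
  √(Q/(J−1)) when Cochran's Q exceeds its expectation. Fixed vs random
  effects is not identified by a single analysis; the multiplicative form is
  the default in the summary-statistic MR literature.
* **MR-Egger**: same regression with a free intercept after orienting
  β_GX ≥ 0; the intercept estimates directional pleiotropy and its test is
  reported. Residual dispersion is floored at 1.
* **Weighted median**: per-variant ratios ordered, weights β_GX²/se_GY²
  normalized, estimate interpolated on the cumulative-weight midpoints at
  0.5. SE by seeded parametric bootstrap (default 1000 draws, both β_GX and
  β_GY perturbed), the original method's approach.
* **Contamination mixture**: each variant's ratio is valid ~ N(θ, se_j²) or
  invalid ~ N(0, ψ² + se_j²); at each θ on a 501-point grid (span of the
  informative ratios extended 25%) variants take their better
  classification and the profile likelihood is maximised. The 95% set
  {θ : 2Δll < 3.84} may be a union of intervals: the hull is the reported
  CI with all modes in the extras. ψ defaults to 1.5× the SD of the
  informative per-variant ratios. "Informative" excludes variants whose
  ratio SE exceeds 10× the median ratio SE: a near-null β_GX produces an
  arbitrarily wild ratio with an equally wild SE that would stretch the
  grid and ψ without adding information (such variants still enter the
  likelihood).

## Multivariable MR and conditional strength

With one GRS per exposure, stage 1 regresses each exposure on all scores
(+ covariates) giving the matrix B; stage 2 fits the outcome on all scores
giving coefficients c with covariance V. Direct effects solve Bᵀθ = c with
delta-method covariance (Bᵀ)⁻¹V B⁻¹ treating B as fixed — first-order, the
right regime when conditional instrument strength is high. Conditional F for
exposure i partials the other exposures' genetically predicted components
out of exposure i and computes the instrument-block F statistic with
numerator degrees of freedom reduced by the number of other exposures
(Sanderson-Windmeijer form). Scores with zero variance are dropped together
with their exposure, which reduces the model to the univariable estimate for
the remaining exposures.

Subgroup differences use the two-sided z test
z = (θ₁−θ₂)/√(se₁²+se₂²); printed OR/HR confidence intervals are converted
back to log-scale SEs as (ln hi − ln lo)/3.92 when comparing published-style
estimates.

## Nonlinear MR

**Doubly-ranked stratification**: individuals are ordered by the instrument
score and cut into consecutive pre-strata of size S; within each pre-stratum
the exposure rank j sends the individual to final stratum j. A final
incomplete pre-stratum of size r sends its members, in exposure order, to
strata 1..r, so stratum sizes differ by at most one (deterministic). Ties
break by exposure, then score, then position. The construction keeps the
instrument's distribution — and its independence from confounders — intact
within every final stratum, which is what validates the stratum-specific
ratio estimate (LACE). Note what is *not* claimed: the confounder itself is
not balanced across strata (stratum means of exposure, and with them the
confounder, increase by construction); the validity property is
within-stratum instrument-confounder independence, and the test suite
verifies exactly that, contrasting it with naive exposure deciles where
conditioning on the exposure (a collider) induces a strong within-stratum
instrument-confounder association.

**Fractional polynomials**: θ̂_k is interpreted as the derivative of the
causal curve h at x̄_k. Candidate models are degree-1 powers
p ∈ {−2,−1,−0.5,0,0.5,1,2} (0 = log) and degree-2 unordered pairs, with
repeated powers using the log-modified basis (x^p, x^p ln x). Each candidate
is fitted by weighted least squares of θ̂_k on the derivative basis with
weights 1/se_k² and known-variance coefficient covariance (XᵀWX)⁻¹; the
selection criterion is the weighted Gaussian log-likelihood, ties broken
toward lower degree then powers nearer p = 1. The curve is the analytic
integral of the fitted derivative, reported relative to a reference exposure
(the sample median by convention, so the curve is exactly 0 there), with
pointwise 95% CIs from the coefficient covariance. Exposures are shifted by
1 − min(x̄) when min(x̄) ≤ 0 before powers are applied; the shift is
inverted on output. Strata without usable estimates (no events, failed
fits) are flagged and excluded with a warning. The nonlinear analysis uses
the raw exposure scale (no rank-normalization): absolute dose-response is
the estimand.

**Tests**: the trend test is the fixed-effect meta-regression of θ̂_k on
x̄_k (normal reference for the slope). The FP nonlinearity test compares
the selected model against the linear model (degree 1, p = 1) by likelihood
ratio against chi-squared with df = 1 for a degree-1 selection (counting
the selected power) and df = 2 for degree-2; if the selected model *is*
linear the p-value is 1 by convention. Both tests hold their nominal size
in the package's replicated calibration experiment (500 cohorts with a
truly linear curve, n = 5000, 50 variants, 10 strata — the sizes were
chosen to make the experiment re-runnable in well under a minute), as
computed by `mrdose.experiments.nonlinearity_calibration` and checked in
the test suite.

## Synthetic cohorts

The generator emulates the statistical structure of a large mid-life
population biobank: 150 independent biallelic variants (MAF uniform on
0.05–0.45) with normal per-allele effects rescaled so the true score
explains exactly `target_r2` = 12% of the unit-variance exposure; a single
standard-normal confounder U loading on the exposure (0.5) and all outcomes
(0.4); recruitment ages uniform on 40–69; disease prevalence ≈ 7%
(intercept −2.86 with the causal curve centred at the median exposure);
three competing causes of death with Weibull cause-specific hazards on the
attained-age timescale (shape 5; rates 0.00513 / 0.0065 / 0.00567 for
cvd / cancer / other), administrative censoring at age 81.5 — giving ≈ 7%
deaths split roughly 20/52/28% — with the causal curve scaled per cause
(1.0 / 0.0 / 0.25 by default). Survival times are drawn conditionally on
being event-free at recruitment (delayed-entry inverse transform), which is
equivalent to resampling individuals whose first event would predate
recruitment; an optional selection model additionally removes individuals
with probability increasing in exposure, emulating survivorship into the
cohort. Principal components are independent standard normals with zero
effect (pure adjustment covariates, 20 of them to mirror the standard
adjustment set); sex is drawn at 54.1% female and has no effect on outcomes
by default. Confounder effect sizes are not observable in real data and
were fixed once at moderate values that make naive regression visibly
biased while MR stays consistent.

What the generator does **not** emulate: linkage disequilibrium,
imputation uncertainty, relatedness, ancestry structure, age-varying
covariate effects, or real phenotype measurement error. Passing tests
therefore demonstrate the estimators' internal validity under the assumed
data-generating process, not robustness to the full messiness of biobank
data.

## Numerical conventions and edge cases

* All effect estimates are kept on the log-odds / log-hazard scale
  internally; exponentiation to OR/HR per exposure SD happens only at
  export.
* p-values from association engines use the normal reference on β/se, and
  a zero SE maps to p = 0 (β ≠ 0) or 1 (β = 0).
* LD pruning is greedy by ascending p-value with lexicographic tie-breaks;
  the r² matrix is an input (computing LD at scale is out of scope).
* One global pipeline seed fans out into fixed per-stage substreams, so
  toggling one stage never perturbs another stage's randomness; the run
  manifest (versions, seed, config hash) suffices to reproduce a run
  bit-identically.
* Degenerate inputs fail loudly: zero variants, constant scores, zero
  events, rank-deficient designs (collinear columns are named), perfect
  separation, singular score-exposure matrices, empty grids.

## Known limitations

* The weighted-median bootstrap ignores between-variant correlation (valid
  for independent, LD-pruned instruments — the intended regime).
* The contamination-mixture CI is grid-quantized (501 points by default).
* MVMR SEs treat the stage-1 coefficient matrix as fixed; with conditional
  F in the tens of thousands in the simulated settings this is negligible,
  but a bootstrap would be needed for honesty near weak-instrument regimes.
* Nonlinear MR here covers the doubly-ranked + fractional-polynomial
  combination only; residual-based stratification and piecewise-linear
  variants are out of scope, as is nonlinear multivariable MR.
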