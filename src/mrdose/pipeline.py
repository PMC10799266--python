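"""End-to-end analysis pipeline: simulate/load -> instruments -> associations
-> linear MR (+ sensitivity suite) -> multivariable MR -> nonlinear MR ->
subgroup z-tests, with tidy-table outputs and a reproducibility manifest.

The pipeline mirrors a standard lipid-MR design: the exposure is inverse
rank-normalized for the linear analysis (comparability across traits) but
left on its raw scale for the nonlinear analysis (absolute dose-response);
disease uses logistic regression with the baseline-age adjustment set;
mortality outcomes use Cox regression on the attained-age timescale with the
birth-year adjustment set and cause-specific censoring. All effect estimates
are kept on the log scale internally and exponentiated only at export.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, instruments, linear, nonlinear, simulate
from .io import write_manifest

__all__ = ["AnalysisConfig", "PipelineError", "run_pipeline", "load_analysis_config"]

log = logging.getLogger("mrdose")

MORTALITY_OUTCOMES = ("all_cause", "cvd", "cancer", "other")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    cohort_path: str | None = None  # delimited cohort table; None -> simulate
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    weight_file: str | None = None  # GWAS weights; None -> simulator's true weights
    outcomes: tuple = ("disease", "all_cause", "cvd", "cancer", "other")
    subgroups: tuple = ("sex", "age65")
    methods: dict = field(
        default_factory=lambda: {
            "ratio": True,
            "sensitivity": True,
            "mvmr": False,
            "nonlinear": True,
        }
    )
    nonlinear_outcomes: tuple = ("disease",)
    n_strata: int = 10
    seed: int = 0
    output_dir: str = "mrdose_out"
    write_cohort: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = simulate._config_to_dict(self.sim)
        return d


def load_analysis_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "sim" in raw:
        raw["sim"] = simulate.config_from_dict(raw["sim"])
    for key in ("outcomes", "subgroups", "nonlinear_outcomes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)


def _stage_seed(seed: int, stage_index: int) -> int:
    """Independent per-stage substream; toggling one stage never perturbs another."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _gy_assoc(cohort, outcome: str, score, table):
    if outcome == "disease":
        covs = assoc.adjustment_matrix(table, "cad_set")
        return assoc.logistic_assoc(table["disease"], score, covs, adjustment_set="cad_set")
    covs = assoc.adjustment_matrix(table, "mortality_set")
    if outcome == "all_cause":
        event = np.asarray(table["event_cause"].astype(str)) != "none"
        return assoc.cox_assoc(
            table["exit_age"], event, score, covs,
            entry_age=table["entry_age"], adjustment_set="mortality_set",
        )
    return assoc.cause_specific_cox(
        table["exit_age"], table["event_cause"], outcome, score, covs,
        entry_age=table["entry_age"], adjustment_set="mortality_set",
    )


def _tidy_row(method, outcome, subgroup, est: linear.MREstimate):
    extras = ";".join(f"{k}={v}" for k, v in est.extras.items() if np.isscalar(v))
    return {
        "method": method,
        "outcome": outcome,
        "subgroup": subgroup,
        "theta": est.theta,
        "se": est.se,
        "ci_low": est.ci95[0],
        "ci_high": est.ci95[1],
        "scale": est.scale,
        "extras": extras,
    }


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the configured analysis; returns the results bundle.

    The bundle maps artifact names to DataFrames (also written as delimited
    text under ``config.output_dir`` together with a JSON manifest holding
    versions, the seed and the config hash). Stage failures re-raise as
    :class:`PipelineError` naming the stage; artifacts already written are
    preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    written: list = []

    def _write(name: str, df: pd.DataFrame):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
        bundle[name] = df

    stage = "simulate"
    try:
        if config.cohort_path is None:
            sim_cfg = dataclasses.replace(config.sim, seed=_stage_seed(config.seed, 0))
            cohort = simulate.simulate_cohort(sim_cfg)
            if config.write_cohort:
                simulate.write_cohort(cohort, out / "cohort.tsv")
                written.append(out / "cohort.tsv")
        else:
            cohort = simulate.read_cohort(config.cohort_path)
        table = cohort.table
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, err) from err

    try:
        stage = "instruments"
        if config.weight_file is not None:
            from .io import read_gwas_table

            wtab = read_gwas_table(config.weight_file)
            weights = instruments.weights_from_table(wtab, source=str(config.weight_file))
        else:
            weights = [
                instruments.VariantWeight(v, "A", float(w), source="simulation-truth")
                for v, w in cohort.true_weights.items()
                if np.isfinite(w)
            ]
        score = instruments.build_grs(cohort.dosages, weights)
        covs_cad = assoc.adjustment_matrix(table, "cad_set")
        diag = instruments.score_strength(score, table["exposure"], covs_cad)
        diag.confounder_assocs = instruments.confounder_check(
            score, table[["sex", "age_at_recruitment"]]
        )
        _write(
            "instrument_diagnostics",
            pd.DataFrame(
                [{"r2": diag.r2, "f_stat": diag.f_stat, "n": diag.n, "weak": diag.weak}]
            ),
        )
        _write("grs_confounder_check", diag.confounder_assocs)

        stage = "associations"
        x_irn = instruments.inverse_rank_normalize(table["exposure"])
        gx = assoc.linear_assoc(x_irn, score, covs_cad, adjustment_set="cad_set")

        results_rows = []
        if config.methods.get("ratio", True):
            stage = "mr_linear"
            for outcome in config.outcomes:
                gy = _gy_assoc(cohort, outcome, score, table)
                est = linear.ratio_estimate(gy, gx)
                results_rows.append(_tidy_row("ratio", outcome, "all", est))
                # subgroups + sex-difference z test
                sub_ests = {}
                for sub in config.subgroups:
                    if sub == "sex":
                        groups = {"male": table["sex"] == 0, "female": table["sex"] == 1}
                    elif sub == "age65":
                        groups = {
                            "age<65": table["age_at_recruitment"] < 65,
                            "age>=65": table["age_at_recruitment"] >= 65,
                        }
                    else:
                        raise ValueError(f"unknown subgroup {sub!r}")
                    for gname, mask in groups.items():
                        sub_t = table.loc[mask].reset_index(drop=True)
                        sub_score = score[np.asarray(mask)]
                        sub_covs = assoc.adjustment_matrix(sub_t, "cad_set")
                        try:
                            sub_x = instruments.inverse_rank_normalize(sub_t["exposure"])
                            sgx = assoc.linear_assoc(sub_x, sub_score, sub_covs)
                            sub_cohort = dataclasses.replace(cohort, table=sub_t)
                            sgy = _gy_assoc(sub_cohort, outcome, sub_score, sub_t)
                            sest = linear.ratio_estimate(sgy, sgx)
                            results_rows.append(_tidy_row("ratio", outcome, gname, sest))
                            sub_ests[gname] = sest
                        except (ValueError, ZeroDivisionError) as err:
                            log.warning("subgroup %s/%s skipped: %s", outcome, gname, err)
                if "male" in sub_ests and "female" in sub_ests:
                    z, p = linear.subgroup_difference_z(sub_ests["male"], sub_ests["female"])
                    results_rows.append(
                        {
                            "method": "sex_difference_z",
                            "outcome": outcome,
                            "subgroup": "male-vs-female",
                            "theta": z,
                            "se": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "scale": "z",
                            "extras": f"p={p:.4g}",
                        }
                    )

        if config.methods.get("sensitivity", True):
            stage = "mr_sensitivity"
            gx_scan = assoc.variant_associations(cohort.dosages, x_irn, "linear", covs_cad)
            gy_scan = assoc.variant_associations(
                cohort.dosages, table["disease"], "logistic", covs_cad
            )
            stats = linear.SummaryStats(
                list(cohort.dosages.columns),
                gx_scan["beta"].to_numpy(),
                gx_scan["se"].to_numpy(),
                gy_scan["beta"].to_numpy(),
                gy_scan["se"].to_numpy(),
            )
            from .io import write_summary_stats

            write_summary_stats(stats, out / "summary_stats_disease.tsv")
            written.append(out / "summary_stats_disease.tsv")
            seed_sens = _stage_seed(config.seed, 3)
            for name, est in [
                ("ivw", linear.ivw(stats)),
                ("egger", linear.mr_egger(stats)),
                ("weighted_median", linear.weighted_median(stats, seed=seed_sens)),
                ("conmix", linear.contamination_mixture(stats)),
            ]:
                results_rows.append(_tidy_row(name, "disease", "all", est))

        if config.methods.get("mvmr", False):
            stage = "mr_mvmr"
            mv_cfg = dataclasses.replace(config.sim, seed=_stage_seed(config.seed, 4))
            mv_cohort, w2, x2 = simulate.simulate_mvmr_cohort(mv_cfg)
            scores = pd.DataFrame(
                {
                    "exposure": instruments.build_grs(
                        mv_cohort.dosages,
                        [
                            instruments.VariantWeight(v, "A", float(w))
                            for v, w in mv_cohort.true_weights.items()
                        ],
                    ),
                    "exposure2": instruments.build_grs(
                        mv_cohort.dosages,
                        [instruments.VariantWeight(v, "A", float(w)) for v, w in w2.items()],
                    ),
                }
            )
            exposures = mv_cohort.table[["exposure", "exposure2"]]
            mv_covs = assoc.adjustment_matrix(mv_cohort.table, "cad_set")
            mv = linear.mvmr_grs(
                scores, exposures, mv_cohort.table["disease"], mv_covs, model="logistic"
            )
            _write(
                "mvmr_results",
                pd.DataFrame(
                    {
                        "exposure": mv.exposures,
                        "theta": mv.theta,
                        "se": mv.se,
                        "ci_low": [c[0] for c in mv.ci95],
                        "ci_high": [c[1] for c in mv.ci95],
                        "conditional_f": mv.conditional_f,
                        "scale": mv.scale,
                        "note": mv.note,
                    }
                ),
            )

        if config.methods.get("nonlinear", True):
            stage = "mr_nonlinear"
            assignment = nonlinear.doubly_ranked_strata(
                score, table["exposure"], config.n_strata
            )
            for outcome in config.nonlinear_outcomes:
                if outcome == "disease":
                    strata = nonlinear.stratum_lace(
                        score,
                        table["exposure"],
                        assignment,
                        table["disease"],
                        model="logistic",
                        covariates=covs_cad,
                    )
                    scale = "logOR"
                else:
                    event = (
                        np.asarray(table["event_cause"].astype(str)) != "none"
                        if outcome == "all_cause"
                        else np.asarray(table["event_cause"].astype(str)) == outcome
                    )
                    strata = nonlinear.stratum_lace(
                        score,
                        table["exposure"],
                        assignment,
                        table["exit_age"],
                        model="cox",
                        covariates=assoc.adjustment_matrix(table, "mortality_set"),
                        entry_age=table["entry_age"],
                        event=event,
                    )
                    scale = "logHR"
                fit = nonlinear.fp_meta_regress(
                    strata, reference_x=float(np.median(table["exposure"])), scale=scale
                )
                _write(
                    f"strata_{outcome}",
                    pd.DataFrame(
                        {
                            "k": [s.k for s in strata],
                            "n_k": [s.n_k for s in strata],
                            "xbar_k": [s.xbar_k for s in strata],
                            "theta_k": [s.theta_k for s in strata],
                            "se_k": [s.se_k for s in strata],
                        }
                    ),
                )
                curve = nonlinear.export_curve(fit)
                curve["p_trend"] = fit.p_trend
                curve["p_fp_nonlinearity"] = fit.p_fp_nonlinearity
                curve["powers"] = ",".join(str(p) for p in fit.powers)
                _write(f"curve_{outcome}", curve)

        stage = "report"
        if results_rows:
            _write("mr_results", pd.DataFrame(results_rows))
        write_manifest(out / "manifest.json", config.to_dict(), config.seed, written)
        written.append(out / "manifest.json")
    except PipelineError:
        raise
    except Exception as err:
        write_manifest(out / "manifest.json", config.to_dict(), config.seed, written)
        raise PipelineError(stage, err) from err

    return bundle
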