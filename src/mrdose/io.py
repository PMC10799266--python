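"""Delimited-text I/O for GWAS-style tables, summary statistics and results."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .linear import SummaryStats

__all__ = [
    "read_gwas_table",
    "read_summary_stats",
    "write_summary_stats",
    "write_manifest",
]

log = logging.getLogger("mrdose")

GWAS_COLUMNS = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "p"]


def read_gwas_table(path) -> pd.DataFrame:
    """Read a GWAS weight file (variant_id, effect_allele, other_allele, eaf, beta, se, p)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    dup = df["variant_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate variant ids: {sorted(df.loc[dup, 'variant_id'].unique())}")
    return df


def read_summary_stats(path) -> SummaryStats:
    """Read merged per-variant summary statistics as a SummaryStats object.

    Required columns: variant_id, beta_gx, se_gx, beta_gy, se_gy, plus
    effect_allele/other_allele. When the optional outcome_effect_allele /
    outcome_other_allele columns are present, rows whose outcome alleles are
    swapped relative to the exposure alleles have beta_gy flipped
    (harmonization); an unresolvable allele pair is an error. Rows with
    missing betas are dropped with the count logged.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["variant_id", "effect_allele", "other_allele", "beta_gx", "se_gx", "beta_gy", "se_gy"]
    for c in required:
        if c not in df.columns:
            raise ValueError(f"missing required column: {c!r}")
    dup = df["variant_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate variant ids: {sorted(df.loc[dup, 'variant_id'].unique())}")

    n0 = len(df)
    df = df.dropna(subset=["beta_gx", "beta_gy"])
    if len(df) < n0:
        log.info("dropped %d row(s) with missing betas", n0 - len(df))
    if len(df) == 0:
        raise ValueError("no variants")

    if "outcome_effect_allele" in df.columns:
        flipped = (df["outcome_effect_allele"] == df["other_allele"]) & (
            df["outcome_other_allele"] == df["effect_allele"]
        )
        aligned = (df["outcome_effect_allele"] == df["effect_allele"]) & (
            df["outcome_other_allele"] == df["other_allele"]
        )
        bad = ~(flipped | aligned)
        if bad.any():
            raise ValueError(
                f"unresolvable allele mismatch for: {sorted(df.loc[bad, 'variant_id'])}"
            )
        df = df.copy()
        df.loc[flipped, "beta_gy"] *= -1.0
        if flipped.any():
            log.info("harmonized %d flipped-allele row(s)", int(flipped.sum()))
    return SummaryStats.from_dataframe(df)


def read_summary_stats_plain(path) -> SummaryStats:
    """Read the plain 5-column layout written by :func:`write_summary_stats`."""
    df = pd.read_csv(path, sep="\t")
    for c in ("variant_id", "beta_gx", "se_gx", "beta_gy", "se_gy"):
        if c not in df.columns:
            raise ValueError(f"missing required column: {c!r}")
    return SummaryStats.from_dataframe(df)


def write_summary_stats(stats: SummaryStats, path) -> None:
    stats.to_dataframe().to_csv(path, sep="\t", index=False)


def write_manifest(path, config_dict: dict, seed: int, outputs: list) -> dict:
    """Run manifest: package/library versions, seed, config hash, artifact list."""
    import numpy, pandas, scipy

    from . import __version__

    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    manifest = {
        "mrdose_version": __version__,
        "numpy_version": numpy.__version__,
        "pandas_version": pandas.__version__,
        "scipy_version": scipy.__version__,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config_dict,
        "outputs": [str(o) for o in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
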