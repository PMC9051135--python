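"""Reading and writing of summary-statistic, LD-reference and cohort tables.

All tables are plain tab-separated text. Summary-statistic tables use the
column set ``variant_id, effect_allele, other_allele, eaf, beta, se, pval, n``.
LD references are three-column ``variant_a, variant_b, r2`` tables. Lines
starting with ``#`` are treated as comments (run metadata is written there).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

LD_COLUMNS = ["variant_a", "variant_b", "r2"]

_VALID_ALLELES = frozenset("ACGT")


class SummaryStatError(ValueError):
    """Raised when a summary-statistic table violates the format contract."""


def _is_biallelic_snp(ea: str, oa: str) -> bool:
    return ea in _VALID_ALLELES and oa in _VALID_ALLELES and ea != oa


def validate_summary_stats(df: pd.DataFrame, *, name: str = "table") -> pd.DataFrame:
    """Validate and clean a summary-statistic frame.

    Duplicate variant ids are a hard error. Indels and multi-allelic records
    (any allele not a single A/C/G/T base) are dropped with a logged count.
    ``se`` must be strictly positive; ``eaf`` may be missing but when present
    must lie in (0, 1). A beta/se vs pval consistency check is warn-only.
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatError(f"{name}: missing columns {missing}")
    df = df.copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    dup = df["variant_id"].duplicated()
    if dup.any():
        raise SummaryStatError(
            f"{name}: duplicate variant ids: {sorted(df.loc[dup, 'variant_id'].unique())[:5]}"
        )

    snp_mask = [
        _is_biallelic_snp(ea, oa)
        for ea, oa in zip(df["effect_allele"], df["other_allele"])
    ]
    n_bad = int(len(df) - np.sum(snp_mask))
    if n_bad:
        logger.warning("%s: dropped %d non-biallelic-SNP records", name, n_bad)
        df = df.loc[snp_mask].reset_index(drop=True)

    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    if (df["se"] <= 0).any() or df["se"].isna().any():
        raise SummaryStatError(f"{name}: se must be positive and present")
    eaf = df["eaf"].dropna()
    if ((eaf <= 0) | (eaf >= 1)).any():
        raise SummaryStatError(f"{name}: eaf must lie in (0, 1) when present")
    pv = df["pval"].dropna()
    if ((pv <= 0) | (pv > 1)).any():
        raise SummaryStatError(f"{name}: pval must lie in (0, 1]")

    # warn-only: |beta/se| should reproduce pval within rounding slack
    ok = df["pval"].notna()
    if ok.any():
        implied = 2 * stats.norm.sf(np.abs(df.loc[ok, "beta"] / df.loc[ok, "se"]))
        bad = np.abs(np.log10(np.maximum(implied, 1e-300)) -
                     np.log10(np.maximum(df.loc[ok, "pval"], 1e-300))) > 1.0
        if bad.any():
            logger.warning(
                "%s: %d records with pval inconsistent with beta/se", name, int(bad.sum())
            )
    return df


def read_summary_stats(path, *, name: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str})
    return validate_summary_stats(df, name=name or str(path))


def write_summary_stats(df: pd.DataFrame, path, *, header_comment: str | None = None) -> None:
    _write_tsv(df[SUMMARY_COLUMNS], path, header_comment)


def read_ld_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_a": str, "variant_b": str})
    missing = [c for c in LD_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatError(f"LD table {path}: missing columns {missing}")
    r2 = pd.to_numeric(df["r2"], errors="coerce")
    if r2.isna().any() or (r2 < 0).any() or (r2 > 1).any():
        raise SummaryStatError(f"LD table {path}: r2 values must lie in [0, 1]")
    df["r2"] = r2
    return df


def write_ld_table(df: pd.DataFrame, path, *, header_comment: str | None = None) -> None:
    _write_tsv(df[LD_COLUMNS], path, header_comment)


def read_cohort(path) -> pd.DataFrame:
    """One row per individual; genotype columns keyed by variant_id."""
    return pd.read_csv(path, sep="\t", comment="#")


def _write_tsv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_table(df: pd.DataFrame, path, *, header_comment: str | None = None) -> None:
    """Write an arbitrary result table in the package TSV dialect."""
    _write_tsv(df, path, header_comment)
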