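"""Allele harmonisation and LD clumping of summary statistics.

Harmonisation aligns outcome effects to the exposure's effect allele,
resolving strand flips via allele complements and palindromic (A/T, C/G)
variants via the allele-frequency rule. Clumping greedily retains the most
significant variant and removes everything in LD with it above a pairwise
r-squared threshold, using an explicit reference table of r-squared values
(missing pairs are treated as independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_summary_stats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_EAF_BAND = (0.42, 0.58)
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_INSTRUMENT_P = 5e-8


class HarmonizationError(ValueError):
    pass


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


@dataclass
class HarmonizedDataset:
    """Instrument-aligned exposure and outcome effects, ready for estimation.

    ``beta_x``/``se_x`` have shape (J, K) for K exposures; ``beta_y``/``se_y``
    have shape (J,). ``flags`` records per-variant provenance including
    dropped variants with their reason.
    """

    variants: list[str]
    exposures: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    flags: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, float))
        if self.beta_x.shape[0] == 1 and len(self.variants) != 1:
            self.beta_x = self.beta_x.T
            self.se_x = self.se_x.T
        self.beta_y = np.asarray(self.beta_y, float)
        self.se_y = np.asarray(self.se_y, float)
        j = len(self.variants)
        if self.beta_x.shape != (j, len(self.exposures)):
            raise ValueError("beta_x shape inconsistent with variants/exposures")
        arrays = (self.beta_x, self.se_x, self.beta_y, self.se_y)
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("harmonized effects must be finite")
        if np.any(self.se_y <= 0) or np.any(self.se_x <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_exposures(self) -> int:
        return len(self.exposures)

    def univariable(self, exposure: str | None = None):
        """(beta_x, se_x, beta_y, se_y) 1-D views for a single exposure."""
        k = 0 if exposure is None else self.exposures.index(exposure)
        return self.beta_x[:, k], self.se_x[:, k], self.beta_y, self.se_y

    def subset(self, variant_ids) -> "HarmonizedDataset":
        keep = [i for i, v in enumerate(self.variants) if v in set(variant_ids)]
        return HarmonizedDataset(
            variants=[self.variants[i] for i in keep],
            exposures=list(self.exposures),
            beta_x=self.beta_x[keep], se_x=self.se_x[keep],
            beta_y=self.beta_y[keep], se_y=self.se_y[keep],
            flags=self.flags,
        )


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    eaf_ambiguity_band: tuple[float, float] = DEFAULT_EAF_BAND,
    exposure_label: str = "exposure",
) -> HarmonizedDataset:
    """Align a single exposure table with an outcome table.

    Rules, applied per shared variant:

    * identical allele labels -> aligned unchanged;
    * swapped labels -> outcome beta negated, eaf replaced by 1 - eaf;
    * complementary (other-strand) labels on non-palindromic variants are
      first mapped back to the exposure strand, then the two rules above;
    * palindromic variants: after label alignment, the two EAFs must both be
      present and outside ``eaf_ambiguity_band``; if they fall on opposite
      sides of 0.5 the coding is inverted (beta negated, eaf flipped), after
      which both lie on the same side -> retained, otherwise dropped;
    * irreconcilable allele pairs dropped with reason ``allele_mismatch``.

    Variants found in only one table are dropped with reason ``missing``.
    Raises :class:`HarmonizationError` when no variant survives.
    """
    lo, hi = eaf_ambiguity_band
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError("eaf_ambiguity_band must lie inside (0, 1)")
    exposure = validate_summary_stats(exposure, name="exposure")
    outcome = validate_summary_stats(outcome, name="outcome")

    out_by_id = outcome.set_index("variant_id")
    flags = []
    kept = []
    exposure_ids = set(exposure["variant_id"])
    for vid in out_by_id.index:
        if vid not in exposure_ids:
            flags.append((vid, "dropped:missing_in_exposure"))
    for row in exposure.itertuples(index=False):
        vid = row.variant_id
        if vid not in out_by_id.index:
            flags.append((vid, "dropped:missing_in_outcome"))
            continue
        orow = out_by_id.loc[vid]
        status, beta_y, se_y, eaf_y = _align_variant(
            row.effect_allele, row.other_allele, row.eaf,
            str(orow["effect_allele"]), str(orow["other_allele"]),
            orow["eaf"], orow["beta"], orow["se"], (lo, hi),
        )
        flags.append((vid, status))
        if not status.startswith("dropped:"):
            kept.append((vid, row.beta, row.se, beta_y, se_y))

    flags_df = pd.DataFrame(flags, columns=["variant_id", "status"])
    if not kept:
        raise HarmonizationError("no variants shared between exposure and outcome survived")
    ids, bx, sx, by, sy = map(list, zip(*kept))
    return HarmonizedDataset(
        variants=ids, exposures=[exposure_label],
        beta_x=np.asarray(bx)[:, None], se_x=np.asarray(sx)[:, None],
        beta_y=np.asarray(by), se_y=np.asarray(sy), flags=flags_df,
    )


def _align_variant(ea_x, oa_x, eaf_x, ea_y, oa_y, eaf_y, beta_y, se_y, band):
    """Return (status, beta_y, se_y, eaf_y) with outcome aligned to exposure."""
    palindromic = _is_palindromic(ea_x, oa_x)
    if not palindromic and not _is_palindromic(ea_y, oa_y):
        # try the other strand when labels do not match directly
        if {ea_y, oa_y} != {ea_x, oa_x}:
            ea_y, oa_y = _COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?")

    if (ea_y, oa_y) == (ea_x, oa_x):
        status = "aligned"
    elif (ea_y, oa_y) == (oa_x, ea_x):
        beta_y = -beta_y
        eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
        status = "flipped"
    else:
        return "dropped:allele_mismatch", None, None, None

    if palindromic:
        lo, hi = band
        if pd.isna(eaf_x) or pd.isna(eaf_y):
            return "dropped:palindromic_ambiguous", None, None, None
        if lo <= eaf_x <= hi or lo <= eaf_y <= hi:
            return "dropped:palindromic_ambiguous", None, None, None
        if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:  # opposite sides: invert coding
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y
        status = "palindromic_resolved"
    return status, beta_y, se_y, eaf_y


def clump(
    candidates: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float = DEFAULT_CLUMP_R2,
) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly retain the remaining variant with the smallest p-value (ties
    broken by lexicographic variant id) and discard all remaining variants
    with reference r2 >= ``r2_threshold`` against it. Pairs absent from the
    reference are treated as r2 = 0. Returns ids in retention order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    if candidates.empty:
        return []
    r2 = pd.to_numeric(ld["r2"], errors="raise") if len(ld) else pd.Series(dtype=float)
    if len(ld) and ((r2 < 0).any() or (r2 > 1).any()):
        raise ValueError("r2 values must lie in [0, 1]")

    neighbours: dict[str, set[str]] = {}
    if len(ld):
        strong = ld.loc[r2.to_numpy() >= r2_threshold]
        for a, b in zip(strong["variant_a"].astype(str), strong["variant_b"].astype(str)):
            neighbours.setdefault(a, set()).add(b)
            neighbours.setdefault(b, set()).add(a)

    order = candidates[["variant_id", "pval"]].copy()
    order["variant_id"] = order["variant_id"].astype(str)
    order = order.sort_values(["pval", "variant_id"], kind="mergesort")
    retained: list[str] = []
    removed: set[str] = set()
    for vid in order["variant_id"]:
        if vid in removed:
            continue
        retained.append(vid)
        removed.add(vid)
        removed |= neighbours.get(vid, set())
    return retained


def clump_multi(
    candidate_sets: dict[str, pd.DataFrame],
    ld: pd.DataFrame,
    r2_threshold: float = DEFAULT_CLUMP_R2,
) -> list[str]:
    """Aggregated clumping across exposures for multivariable MR.

    The union of all per-exposure candidates is clumped as one set, each
    variant carrying its minimum p-value across the exposures that propose it.
    """
    if not candidate_sets:
        raise ValueError("candidate_sets must not be empty")
    frames = []
    for name, df in candidate_sets.items():
        frames.append(df[["variant_id", "pval"]].assign(variant_id=df["variant_id"].astype(str)))
    merged = (pd.concat(frames, ignore_index=True)
              .groupby("variant_id", as_index=False)["pval"].min())
    return clump(merged, ld, r2_threshold)


def assert_independent(retained, ld: pd.DataFrame, r2_threshold: float) -> None:
    """Post-hoc invariant check: no retained pair is in LD above threshold."""
    kept = set(retained)
    if not len(ld):
        return
    bad = ld[(ld["variant_a"].astype(str).isin(kept))
             & (ld["variant_b"].astype(str).isin(kept))
             & (ld["r2"] >= r2_threshold)]
    if len(bad):
        raise AssertionError(f"clump output not independent: {bad.head().to_dict('records')}")


def merge_exposures(datasets: dict[str, HarmonizedDataset],
                    variant_ids) -> HarmonizedDataset:
    """Build a K-exposure dataset from per-exposure harmonized datasets.

    Only variants present in every per-exposure dataset and in ``variant_ids``
    are retained; outcome effects are taken from the first dataset (all are
    harmonized against the same outcome).
    """
    names = list(datasets)
    common = set(variant_ids)
    for ds in datasets.values():
        common &= set(ds.variants)
    first = datasets[names[0]]
    ordered = [v for v in first.variants if v in common]
    if not ordered:
        raise HarmonizationError("no variants shared across all exposures")
    index = {name: {v: i for i, v in enumerate(ds.variants)}
             for name, ds in datasets.items()}
    j, k = len(ordered), len(names)
    beta_x = np.empty((j, k))
    se_x = np.empty((j, k))
    for ki, name in enumerate(names):
        ds = datasets[name]
        rows = [index[name][v] for v in ordered]
        beta_x[:, ki] = ds.beta_x[rows, 0]
        se_x[:, ki] = ds.se_x[rows, 0]
    rows0 = [index[names[0]][v] for v in ordered]
    return HarmonizedDataset(
        variants=ordered, exposures=names,
        beta_x=beta_x, se_x=se_x,
        beta_y=first.beta_y[rows0], se_y=first.se_y[rows0],
        flags=first.flags,
    )


def select_instruments(table: pd.DataFrame, p_threshold: float = DEFAULT_INSTRUMENT_P) -> pd.DataFrame:
    """Genome-wide-significance instrument selection (p below threshold)."""
    return table.loc[table["pval"] < p_threshold].reset_index(drop=True)
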