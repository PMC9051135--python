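"""Reverse-direction genetic-risk-score regression, Benjamini-Hochberg FDR
control, and the constant-relative-risk category-shift intervention model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class InstrumentSet:
    """Per-variant weights (log-odds for a liability score) keyed by id."""

    variant_ids: tuple[str, ...]
    weights: tuple[float, ...]
    effect_alleles: tuple[str, ...] | None = None
    eafs: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.variant_ids) < 1:
            raise ValueError("instrument set must contain at least one variant")
        if len(self.weights) != len(self.variant_ids):
            raise ValueError("weights must match variant_ids")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InstrumentSet":
        return cls(
            variant_ids=tuple(df["variant_id"].astype(str)),
            weights=tuple(df["weight"].astype(float)),
            effect_alleles=tuple(df["effect_allele"]) if "effect_allele" in df else None,
            eafs=tuple(df["eaf"].astype(float)) if "eaf" in df else None,
        )


@dataclass
class GRSResult:
    beta: float  # per 1-SD change in the score
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n: int
    covariates: tuple[str, ...]


def grs_regression(cohort: pd.DataFrame, instruments: InstrumentSet,
                   covariates=("age", "sex"),
                   phenotype: str = "phenotype") -> GRSResult:
    """OLS of phenotype on a standardized weighted allele score plus covariates.

    The score is the weighted sum of effect-allele dosages, standardized to
    mean 0 / SD 1 within the cohort, so the slope reads "per 1-SD change in
    the score". Standardization makes the slope invariant to rescaling all
    weights by a positive constant.
    """
    missing = [v for v in instruments.variant_ids if v not in cohort.columns]
    if missing:
        raise ValueError(f"instruments absent from cohort genotypes: {missing[:5]}")
    dosage = cohort[list(instruments.variant_ids)].to_numpy(float)
    score = dosage @ np.asarray(instruments.weights)
    sd = score.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance genetic risk score")
    grs = (score - score.mean()) / sd

    design = pd.DataFrame({"grs": grs}, index=cohort.index)
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} absent from cohort")
        design[cov] = cohort[cov].to_numpy(float)
    fit = sm.OLS(cohort[phenotype].to_numpy(float), sm.add_constant(design)).fit()
    ci = fit.conf_int().loc["grs"]
    return GRSResult(beta=float(fit.params["grs"]), se=float(fit.bse["grs"]),
                     ci_low=float(ci[0]), ci_high=float(ci[1]),
                     pval=float(fit.pvalues["grs"]), n=int(fit.nobs),
                     covariates=tuple(covariates))


def bh_fdr(pvals, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment.

    Returns a frame aligned with the input order carrying the adjusted
    p-value (min over k >= rank of p_(k) * m / k, capped at 1) and the
    pass flag ``adjusted <= q``.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return pd.DataFrame({"pval": p, "adjusted": adjusted, "pass": adjusted <= q})


@dataclass(frozen=True)
class InterventionScenario:
    """Ordered body-size categories with a constant relative risk per
    one-category increase; ``shift`` moves that fraction of the population
    from each non-bottom category down one category (cascade)."""

    category_proportions: tuple[float, ...]
    rr_per_category: float
    baseline_prevalence: float
    shift: float
    category_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        p = np.asarray(self.category_proportions, float)
        if len(p) < 2:
            raise ValueError("need at least two categories")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("category proportions must sum to 1 (tolerance 1e-12)")
        if np.any(p < 0):
            raise ValueError("category proportions must be non-negative")
        if self.rr_per_category <= 0:
            raise ValueError("relative risk must be positive")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline prevalence must lie in (0, 1)")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")
        if np.any(self.shifted_proportions() < -1e-15):
            raise ValueError("shift larger than a category proportion")

    def shifted_proportions(self) -> np.ndarray:
        p = np.asarray(self.category_proportions, float).copy()
        for i in range(len(p) - 1, 0, -1):
            p[i] -= self.shift
            p[i - 1] += self.shift
        return p


@dataclass
class InterventionResult:
    baseline_prevalence: float
    post_prevalence: float
    post_prevalence_pct_rounded: float  # percentage, 2 decimals
    percent_reduction: float            # from unrounded prevalences
    percent_reduction_from_rounded: float
    bottom_category_risk: float
    risk_by_category: np.ndarray
    proportion_table: pd.DataFrame


def intervention_model(scenario: InterventionScenario) -> InterventionResult:
    """Constant-RR category-shift prevalence model.

    The bottom-category risk r solves
    ``baseline_prevalence = r * sum_i p_i * RR^i`` (categories ordered from
    lowest to highest risk); the post-shift prevalence re-weights the same
    per-category risks by the shifted proportions. The percent reduction is
    reported both at full precision and as recomputed from the prevalence
    rounded to two decimal places on the percentage scale.
    """
    p = np.asarray(scenario.category_proportions, float)
    c = len(p)
    rr_powers = scenario.rr_per_category ** np.arange(c)
    r = scenario.baseline_prevalence / float(p @ rr_powers)
    risks = r * rr_powers
    if np.any(risks >= 1.0):
        raise ValueError("implied per-category risk exceeds 1; scenario infeasible")
    p_shift = scenario.shifted_proportions()
    post = float(p_shift @ risks)

    prev = scenario.baseline_prevalence
    post_pct_rounded = round(post * 100, 2)
    reduction = 100.0 * (1.0 - post / prev)
    reduction_rounded = 100.0 * (prev * 100 - post_pct_rounded) / (prev * 100)

    labels = scenario.category_labels or tuple(f"category_{i}" for i in range(c))
    affected = p * risks / prev
    unaffected = p * (1.0 - risks) / (1.0 - prev)
    table = pd.DataFrame({
        "category": labels,
        "proportion": p,
        "shifted_proportion": p_shift,
        "risk": risks,
        "affected_proportion": affected,
        "unaffected_proportion": unaffected,
    })
    return InterventionResult(
        baseline_prevalence=prev, post_prevalence=post,
        post_prevalence_pct_rounded=post_pct_rounded,
        percent_reduction=reduction,
        percent_reduction_from_rounded=reduction_rounded,
        bottom_category_risk=float(r), risk_by_category=risks,
        proportion_table=table)
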