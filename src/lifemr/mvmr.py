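"""Multivariable MR: joint direct-effect estimation across K exposures and
the total/direct/indirect decomposition."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, _heterogeneity_stats, _pfloor
from .harmonization import HarmonizedDataset

logger = logging.getLogger(__name__)

_CONDITION_WARN = 1e6


@dataclass
class MVMRModel:
    """Fitted multivariable model: one direct-effect estimate per exposure."""

    exposures: list[str]
    estimates: dict[str, MREstimate]
    method: str
    n_snps: int
    Q: float
    Q_df: int
    Q_pval: float
    intercept: float | None = None
    se_intercept: float | None = None
    pval_intercept: float | None = None

    def __getitem__(self, exposure: str) -> MREstimate:
        return self.estimates[exposure]


def _check_rank(x: np.ndarray, exposures) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"exposure effect matrix is rank deficient; collinear exposures among {exposures}")
    cond = np.linalg.cond(x)
    if cond > _CONDITION_WARN:
        logger.warning("near-collinear exposures %s (condition number %.3g)", exposures, cond)


def _weighted_fit(design, by, w, k_effects, df, dist):
    """Weighted normal-equation fit with multiplicative SE inflation."""
    xtw = design.T * w
    cov_unscaled = np.linalg.inv(xtw @ design)
    coefs = cov_unscaled @ (xtw @ by)
    resid = by - design @ coefs
    q = float(np.sum(w * resid ** 2))
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    if dist == "t":
        pvals = _pfloor(2 * stats.t.sf(np.abs(coefs) / ses, df))
        crit = stats.t.ppf(0.975, df)
    else:
        pvals = _pfloor(2 * stats.norm.sf(np.abs(coefs) / ses))
        crit = stats.norm.ppf(0.975)
    return coefs, ses, pvals, crit, q


def mvmr_ivw(dataset: HarmonizedDataset, outcome: str = "outcome") -> MVMRModel:
    """Multivariable IVW: weighted no-intercept regression of outcome effects
    on the K exposure-effect columns (weights 1/se_y^2). Each coefficient is
    the direct effect of that exposure conditional on the others; SEs carry
    multiplicative random-effects inflation max(1, sqrt(Q/(J-K))) and
    p-values use t with J-K degrees of freedom.
    """
    x = dataset.beta_x
    j, k = x.shape
    if j < k + 1:
        raise ValueError(f"need at least K+1={k + 1} variants, got {j}")
    _check_rank(x, dataset.exposures)
    w = 1.0 / dataset.se_y ** 2
    df = j - k
    coefs, ses, pvals, crit, q = _weighted_fit(x, dataset.beta_y, w, k, df, "t")
    q, qdf, q_pval, i2 = _heterogeneity_stats(q, df)
    estimates = {}
    for ki, name in enumerate(dataset.exposures):
        estimates[name] = MREstimate(
            method="mvmr_ivw", theta=float(coefs[ki]), se=float(ses[ki]),
            ci_low=float(coefs[ki] - crit * ses[ki]),
            ci_high=float(coefs[ki] + crit * ses[ki]),
            pval=float(pvals[ki]), n_snps=j, exposure=name, outcome=outcome,
            Q=q, Q_df=qdf, Q_pval=q_pval, I2=i2)
    return MVMRModel(exposures=list(dataset.exposures), estimates=estimates,
                     method="mvmr_ivw", n_snps=j, Q=q, Q_df=qdf, Q_pval=q_pval)


def mvmr_egger(dataset: HarmonizedDataset, focal_exposure: str | None = None,
               outcome: str = "outcome") -> MVMRModel:
    """Multivariable MR-Egger with orientation on one focal exposure.

    Every variant is oriented so the focal exposure's effect is non-negative
    (negating that variant's entries across all exposures and the outcome),
    then a weighted regression with intercept is fitted; the intercept test
    reports directional pleiotropy. t(J-K-1) p-values.
    """
    x = dataset.beta_x.copy()
    by = dataset.beta_y.copy()
    j, k = x.shape
    if j < k + 2:
        raise ValueError(f"need at least K+2={k + 2} variants, got {j}")
    focal = 0 if focal_exposure is None else dataset.exposures.index(focal_exposure)
    sign = np.where(x[:, focal] < 0, -1.0, 1.0)
    x *= sign[:, None]
    by *= sign
    design = np.column_stack([np.ones(j), x])
    _check_rank(design, dataset.exposures)
    w = 1.0 / dataset.se_y ** 2
    df = j - k - 1
    coefs, ses, pvals, crit, q = _weighted_fit(design, by, w, k + 1, df, "t")
    q, qdf, q_pval, i2 = _heterogeneity_stats(q, df)
    estimates = {}
    for ki, name in enumerate(dataset.exposures):
        c, s, p = coefs[ki + 1], ses[ki + 1], pvals[ki + 1]
        estimates[name] = MREstimate(
            method="mvmr_egger", theta=float(c), se=float(s),
            ci_low=float(c - crit * s), ci_high=float(c + crit * s),
            pval=float(p), n_snps=j, exposure=name, outcome=outcome,
            intercept=float(coefs[0]), se_intercept=float(ses[0]),
            pval_intercept=float(pvals[0]),
            Q=q, Q_df=qdf, Q_pval=q_pval, I2=i2)
    return MVMRModel(exposures=list(dataset.exposures), estimates=estimates,
                     method="mvmr_egger", n_snps=j, Q=q, Q_df=qdf, Q_pval=q_pval,
                     intercept=float(coefs[0]), se_intercept=float(ses[0]),
                     pval_intercept=float(pvals[0]))


@dataclass
class EffectDecomposition:
    """Total = direct + indirect on the log-odds scale.

    The indirect SE assumes independence of the total and direct estimates
    and is therefore approximate. Classification: ``direct`` when the direct
    CI excludes 0; ``mediated`` when the total CI excludes 0 but the direct
    CI includes it; ``none`` otherwise.
    """

    exposure: str
    outcome: str
    total: float
    direct: float
    indirect: float
    se_indirect_approx: float
    classification: str


def decompose_effects(total: MREstimate, direct: MREstimate) -> EffectDecomposition:
    if (total.exposure, total.outcome) != (direct.exposure, direct.outcome):
        raise ValueError("total and direct estimates refer to different exposure/outcome")
    indirect = total.theta - direct.theta
    se = float(np.sqrt(total.se ** 2 + direct.se ** 2))
    direct_nonnull = direct.ci_low > 0 or direct.ci_high < 0
    total_nonnull = total.ci_low > 0 or total.ci_high < 0
    if direct_nonnull:
        classification = "direct"
    elif total_nonnull:
        classification = "mediated"
    else:
        classification = "none"
    return EffectDecomposition(
        exposure=total.exposure, outcome=total.outcome,
        total=total.theta, direct=direct.theta, indirect=float(indirect),
        se_indirect_approx=se, classification=classification)
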