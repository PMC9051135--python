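"""Univariable two-sample MR estimators: Wald ratio, IVW, MR-Egger,
weighted median, and heterogeneity diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .harmonization import HarmonizedDataset


@dataclass
class MREstimate:
    """One estimator's causal-effect result on the log-odds scale.

    ``or_``, ``or_lcl`` and ``or_ucl`` expose the exp-transformed estimate and
    confidence interval. For Egger-type methods the intercept (directional
    pleiotropy) test is reported alongside the slope.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    exposure: str = "exposure"
    outcome: str = "outcome"
    intercept: float | None = None
    se_intercept: float | None = None
    pval_intercept: float | None = None
    Q: float | None = None
    Q_df: int | None = None
    Q_pval: float | None = None
    I2: float | None = None
    seed: int | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.theta))

    @property
    def or_lcl(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ucl(self) -> float:
        return float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["or"] = self.or_
        d["or_lcl"] = self.or_lcl
        d["or_ucl"] = self.or_ucl
        return d


def _pfloor(p):
    """Keep p-values strictly positive (two-sided tails can underflow)."""
    return np.maximum(p, np.finfo(float).tiny)


def _norm_ci(theta: float, se: float, level: float = 0.95):
    z = stats.norm.ppf(0.5 + level / 2)
    return theta - z * se, theta + z * se


def _heterogeneity_stats(q: float, df: int):
    q = float(q)
    q_pval = float(stats.chi2.sf(q, df)) if df > 0 else np.nan
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, q_pval, i2


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               exposure: str = "exposure", outcome: str = "outcome") -> MREstimate:
    """Single-variant ratio estimate, first-order (NOME) standard error."""
    if beta_x == 0:
        raise ValueError("undefined ratio: beta_x = 0")
    theta = beta_y / beta_x
    se = se_y / abs(beta_x)
    lo, hi = _norm_ci(theta, se)
    pval = _pfloor(2 * stats.norm.sf(abs(theta) / se)) if se > 0 else float(theta == 0)
    return MREstimate(method="wald", theta=theta, se=se, ci_low=lo, ci_high=hi,
                      pval=pval, n_snps=1, exposure=exposure, outcome=outcome)


def ivw(dataset: HarmonizedDataset, effects_model: str = "multiplicative_random",
        exposure: str | None = None, outcome: str = "outcome") -> MREstimate:
    """Inverse-variance-weighted estimate (origin-constrained weighted
    regression of outcome effects on exposure effects).

    ``effects_model`` is ``fixed`` or ``multiplicative_random``; the latter
    inflates the fixed-effect SE by max(1, sqrt(Q/(J-1))).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    bx, _, by, sy = dataset.univariable(exposure)
    j = len(bx)
    if j < 1 or (effects_model == "multiplicative_random" and j < 2):
        raise ValueError("too few variants for IVW")
    if np.all(bx == 0):
        raise ValueError("all exposure effects are zero")
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * bx ** 2))
    theta = float(np.sum(w * bx * by) / denom)
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (j - 1)))
        method = "ivw_re"
    else:
        se = se_fixed
        method = "ivw_fe"
    lo, hi = _norm_ci(theta, se)
    pval = _pfloor(2 * stats.norm.sf(abs(theta) / se))
    q, df, q_pval, i2 = _heterogeneity_stats(q, j - 1)
    return MREstimate(method=method, theta=theta, se=se, ci_low=lo, ci_high=hi,
                      pval=float(pval), n_snps=j, Q=q, Q_df=df, Q_pval=q_pval,
                      I2=i2, exposure=exposure or dataset.exposures[0],
                      outcome=outcome)


def egger(dataset: HarmonizedDataset, exposure: str | None = None,
          outcome: str = "outcome") -> MREstimate:
    """MR-Egger: weighted regression with an unconstrained intercept.

    Variants are oriented so exposure effects are non-negative; slope and
    intercept SEs are inflated by max(1, sqrt(Q/(J-2))) and p-values use a
    t distribution with J-2 degrees of freedom. The intercept test is the
    directional-pleiotropy diagnostic.
    """
    bx, _, by, sy = dataset.univariable(exposure)
    j = len(bx)
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise ValueError("zero variance in oriented exposure effects; slope unidentified")
    w = 1.0 / sy ** 2
    design = np.column_stack([np.ones(j), bx])
    xtw = design.T * w
    cov_unscaled = np.linalg.inv(xtw @ design)
    coefs = cov_unscaled @ (xtw @ by)
    resid = by - design @ coefs
    q = float(np.sum(w * resid ** 2))
    df = j - 2
    scale = max(1.0, np.sqrt(q / df))
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    tcrit = stats.t.ppf(0.975, df)
    alpha, theta = float(coefs[0]), float(coefs[1])
    se_a, se_t = float(ses[0]), float(ses[1])
    pval = _pfloor(2 * stats.t.sf(abs(theta) / se_t, df))
    pval_a = _pfloor(2 * stats.t.sf(abs(alpha) / se_a, df))
    q, qdf, q_pval, i2 = _heterogeneity_stats(q, df)
    return MREstimate(method="egger", theta=theta, se=se_t,
                      ci_low=theta - tcrit * se_t, ci_high=theta + tcrit * se_t,
                      pval=float(pval), n_snps=j,
                      intercept=alpha, se_intercept=se_a, pval_intercept=float(pval_a),
                      Q=q, Q_df=qdf, Q_pval=q_pval, I2=i2,
                      exposure=exposure or dataset.exposures[0], outcome=outcome)


def weighted_median(dataset: HarmonizedDataset, n_boot: int = 1000,
                    seed: int = 0, exposure: str | None = None,
                    outcome: str = "outcome") -> MREstimate:
    """Weighted-median estimate with a parametric-bootstrap standard error.

    Per-variant Wald ratios are weighted by (beta_x/se_y)^2; the estimate is
    the weighted 50th percentile obtained by linear interpolation of the
    cumulative weight function over the sorted ratios. Variants with
    beta_x = 0 are excluded.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bx, sx, by, sy = dataset.univariable(exposure)
    valid = bx != 0
    if not valid.all():
        import logging
        logging.getLogger(__name__).warning(
            "weighted_median: excluded %d variants with beta_x = 0", int((~valid).sum()))
    bx, sx, by, sy = bx[valid], sx[valid], by[valid], sy[valid]
    j = len(bx)
    if j < 3:
        raise ValueError("weighted median requires at least 3 usable variants")
    theta = _weighted_median_point(bx, by, sy)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(j)
        by_b = by + sy * rng.standard_normal(j)
        ok = bx_b != 0
        boots[b] = _weighted_median_point(bx_b[ok], by_b[ok], sy[ok])
    se = float(boots.std(ddof=1))
    lo, hi = _norm_ci(theta, se)
    pval = _pfloor(2 * stats.norm.sf(abs(theta) / se)) if se > 0 else float(theta == 0)
    return MREstimate(method="weighted_median", theta=float(theta), se=se,
                      ci_low=lo, ci_high=hi, pval=float(pval), n_snps=j,
                      seed=seed, exposure=exposure or dataset.exposures[0],
                      outcome=outcome)


def _weighted_median_point(bx, by, sy) -> float:
    ratios = by / bx
    weights = (bx / sy) ** 2
    weights = weights / weights.sum()
    order = np.argsort(ratios, kind="mergesort")
    ratios, weights = ratios[order], weights[order]
    cum = np.cumsum(weights) - weights / 2
    return float(np.interp(0.5, cum, ratios))


def heterogeneity(dataset: HarmonizedDataset, theta: float,
                  exposure: str | None = None):
    """Cochran's Q about a given slope, with df = J - 1.

    Returns ``(Q, df, pval_Q, I2)`` where I2 = max(0, (Q - df)/Q).
    """
    bx, _, by, sy = dataset.univariable(exposure)
    j = len(bx)
    if j < 2:
        raise ValueError("heterogeneity requires J > df")
    w = 1.0 / sy ** 2
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return _heterogeneity_stats(q, j - 1)
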