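"""Independent oracle implementations used to check the package estimators.

These deliberately take different code paths from src/lifemr: regressions go
through statsmodels WLS, clumping is a literal O(n^2) re-enactment of the
greedy rule over an explicit r2 matrix, the weighted median is a loop-based
cumulative-weight search, and BH adjustment defers to statsmodels.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


def wls_oracle(x, y, weights, *, intercept: bool):
    """Weighted least squares via statsmodels, with the multiplicative
    random-effects SE inflation max(1, sqrt(Q/df)) applied on top.

    Returns (coefs, ses, Q, df); when ``intercept`` the intercept comes first.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1 and len(y) != 1:
        x = x.T
    design = sm.add_constant(x, has_constant="add") if intercept else x
    fit = sm.WLS(np.asarray(y, float), design, weights=np.asarray(weights, float)).fit()
    q = float(fit.ssr)  # weighted residual sum of squares
    df = int(fit.df_resid)
    se_unscaled = fit.bse / np.sqrt(fit.scale)
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    return np.asarray(fit.params), np.asarray(se_unscaled * scale), q, df


def ivw_oracle(bx, by, sy):
    """Origin-constrained WLS with weights 1/sy^2 (fixed + random SEs)."""
    coefs, ses, q, df = wls_oracle(np.asarray(bx)[:, None], by, 1.0 / np.asarray(sy) ** 2,
                                   intercept=False)
    return float(coefs[0]), float(ses[0]), q, df


def egger_oracle(bx, by, sy):
    """Intercept-including WLS after orienting exposure effects >= 0."""
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    sign = np.where(bx < 0, -1.0, 1.0)
    coefs, ses, q, df = wls_oracle((bx * sign)[:, None], by * sign,
                                   1.0 / np.asarray(sy) ** 2, intercept=True)
    return coefs, ses, q, df


def mvmr_oracle(bx, by, sy, *, intercept: bool, focal: int = 0):
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    if intercept:
        sign = np.where(bx[:, focal] < 0, -1.0, 1.0)
        bx, by = bx * sign[:, None], by * sign
    return wls_oracle(bx, by, 1.0 / np.asarray(sy) ** 2, intercept=intercept)


def weighted_median_oracle(bx, by, sy):
    """Loop-based cumulative-weight interpolation at probability 0.5."""
    ratios = np.asarray(by, float) / np.asarray(bx, float)
    w = (np.asarray(bx, float) / np.asarray(sy, float)) ** 2
    w = w / w.sum()
    order = np.argsort(ratios)
    ratios, w = ratios[order], w[order]
    cum = 0.0
    points = []
    for ri, wi in zip(ratios, w):
        points.append((cum + wi / 2.0, ri))
        cum += wi
    # piecewise-linear inverse CDF evaluated at 0.5
    if 0.5 <= points[0][0]:
        return points[0][1]
    for (c0, r0), (c1, r1) in zip(points, points[1:]):
        if c0 <= 0.5 <= c1:
            return r0 + (r1 - r0) * (0.5 - c0) / (c1 - c0)
    return points[-1][1]


def clump_oracle(variant_ids, pvals, r2_matrix, threshold):
    """Literal greedy enumeration over an explicit symmetric r2 matrix."""
    ids = list(map(str, variant_ids))
    pvals = list(map(float, pvals))
    remaining = list(range(len(ids)))
    retained = []
    while remaining:
        best = min(remaining, key=lambda i: (pvals[i], ids[i]))
        retained.append(ids[best])
        remaining = [i for i in remaining
                     if i != best and r2_matrix[best][i] < threshold]
    return retained


def bh_oracle(pvals):
    _, adjusted, _, _ = multipletests(np.asarray(pvals, float), method="fdr_bh")
    return adjusted
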