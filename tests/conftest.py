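import numpy as np
import pandas as pd
import pytest

from lifemr.harmonization import HarmonizedDataset
from lifemr.io import SUMMARY_COLUMNS
from lifemr.simulate import SimulationConfig


def make_summary_table(variant_ids, beta, se, ea="A", oa="G", eaf=0.3, n=10000,
                       pval=None):
    """Build a minimal valid summary-statistic frame."""
    from scipy import stats

    j = len(variant_ids)
    beta = np.broadcast_to(np.asarray(beta, float), (j,))
    se = np.broadcast_to(np.asarray(se, float), (j,))
    if pval is None:
        pval = 2 * stats.norm.sf(np.abs(beta / se))
        pval = np.maximum(pval, np.finfo(float).tiny)
    return pd.DataFrame({
        "variant_id": variant_ids,
        "effect_allele": np.broadcast_to(np.asarray(ea, object), (j,)),
        "other_allele": np.broadcast_to(np.asarray(oa, object), (j,)),
        "eaf": np.broadcast_to(np.asarray(eaf, float), (j,)),
        "beta": beta, "se": se,
        "pval": np.broadcast_to(np.asarray(pval, float), (j,)),
        "n": n,
    })[SUMMARY_COLUMNS]


def make_dataset(bx, sx, by, sy, exposures=("exposure",)) -> HarmonizedDataset:
    bx = np.asarray(bx, float)
    if bx.ndim == 1:
        bx = bx[:, None]
    sx = np.asarray(sx, float)
    if sx.ndim == 0:
        sx = np.full(bx.shape, float(sx))
    elif sx.ndim == 1:
        sx = np.broadcast_to(sx[:, None], bx.shape).copy()
    j = bx.shape[0]
    by = np.broadcast_to(np.asarray(by, float), (j,))
    sy = np.broadcast_to(np.asarray(sy, float), (j,))
    return HarmonizedDataset(
        variants=[f"rs{i}" for i in range(j)],
        exposures=list(exposures),
        beta_x=bx, se_x=sx, beta_y=by.copy(), se_y=sy.copy(),
    )


def random_dataset(rng, j=8, k=1):
    """Small random dataset for oracle-equivalence checks."""
    bx = rng.normal(0.0, 0.2, size=(j, k))
    sx = rng.uniform(0.01, 0.05, size=(j, k))
    by = rng.normal(0.0, 0.2, size=j)
    sy = rng.uniform(0.02, 0.2, size=j)
    return make_dataset(bx, sx, by, sy,
                        exposures=[f"x{i}" for i in range(k)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240905)


@pytest.fixture
def base_config():
    return SimulationConfig(seed=11)


@pytest.fixture
def small_config():
    return SimulationConfig(
        exposures=("childhood", "adult"), n_instruments=(40, 60),
        true_effects=(np.log(2.0), 0.0), seed=11)
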