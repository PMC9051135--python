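"""Synthetic two-sample GWAS summary statistics and a small genotyped cohort.

Summary statistics are generated directly at the summary level under normal
sampling theory: per-variant exposure effects are drawn from a zero-mean
(multivariate) normal with a configurable between-exposure correlation, the
outcome effect is the causal combination of the exposure effects plus an
optional pleiotropy term, and estimation noise is scaled as 1/sqrt(n) of the
respective study. Allele codings in the outcome table can be corrupted
(effect/other swaps; strand flips on palindromic variants) to exercise the
harmonisation stage, and a block-structured LD reference can be emitted to
exercise clumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SUMMARY_COLUMNS

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic GWAS generator.

    ``n_instruments`` gives the number of variants assigned to each exposure
    (e.g. 280 childhood, 515 adult, 161 birthweight); every variant carries an
    effect on every exposure so that between-exposure correlation is
    meaningful. ``true_effects`` are direct causal effects on the log-odds
    scale. ``noise_scale`` multiplies the added estimation noise only
    (reported standard errors stay at their theoretical 1/sqrt(n) values), so
    0 yields noiseless identities with usable SEs.
    """

    exposures: tuple[str, ...] = ("childhood", "adult")
    n_instruments: tuple[int, ...] = (280, 515)
    true_effects: tuple[float, ...] = (np.log(2.0), 0.0)
    exposure_correlation: float = 0.0
    effect_sd: float = 0.05
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exposure_sample: int = 453_169
    n_outcome_sample: int = 15_000
    eaf_range: tuple[float, float] = (0.10, 0.90)
    frac_palindromic: float = 0.0
    frac_allele_swapped: float = 0.0
    ambiguous_palindromic: bool = False
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    noise_scale: float = 1.0
    orient_instruments: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.n_instruments) != len(self.exposures):
            raise ValueError("n_instruments must match exposures")
        if len(self.true_effects) != len(self.exposures):
            raise ValueError("true_effects must match exposures")
        if any(n < 1 for n in self.n_instruments):
            raise ValueError("instrument counts must be positive")
        if self.n_exposure_sample < 2 or self.n_outcome_sample < 2:
            raise ValueError("sample sizes must be >= 2")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range must be strictly inside (0, 1)")
        if not -1.0 <= self.exposure_correlation <= 1.0:
            raise ValueError("exposure_correlation must lie in [-1, 1]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.pleiotropy != "directional" and self.pleiotropy_mean != 0.0:
            raise ValueError("pleiotropy_mean must be 0 unless pleiotropy='directional'")
        for frac, name in ((self.frac_palindromic, "frac_palindromic"),
                           (self.frac_allele_swapped, "frac_allele_swapped")):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.ld_blocks is not None:
            total = sum(size for size, _ in self.ld_blocks)
            if total > sum(self.n_instruments):
                raise ValueError("LD blocks exceed instrument count")
            if any(size < 1 for size, _ in self.ld_blocks):
                raise ValueError("LD block sizes must be positive")
            if any(not 0.0 <= r2 <= 1.0 for _, r2 in self.ld_blocks):
                raise ValueError("LD block r2 must lie in [0, 1]")

    @property
    def n_variants(self) -> int:
        return sum(self.n_instruments)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SummaryPair:
    """Output of :func:`simulate_summary_pair`."""

    exposure_tables: dict[str, pd.DataFrame]
    outcome_table: pd.DataFrame
    truth: pd.DataFrame
    ld_table: pd.DataFrame
    config: SimulationConfig

    def to_harmonized(self, exposures: Sequence[str] | None = None):
        """Assemble a HarmonizedDataset directly, bypassing allele alignment.

        Only valid when the generating config applied no allele corruption
        (``frac_allele_swapped == 0``); raises otherwise. Intended for
        simulation studies where the harmonisation stage is not under test.
        """
        if self.config.frac_allele_swapped > 0:
            raise ValueError("tables are corrupted; run harmonize() instead")
        from .harmonization import HarmonizedDataset

        names = list(exposures) if exposures is not None else list(self.config.exposures)
        beta_x = np.column_stack([self.exposure_tables[n]["beta"].to_numpy() for n in names])
        se_x = np.column_stack([self.exposure_tables[n]["se"].to_numpy() for n in names])
        return HarmonizedDataset(
            variants=list(self.outcome_table["variant_id"]),
            exposures=names, beta_x=beta_x, se_x=se_x,
            beta_y=self.outcome_table["beta"].to_numpy(),
            se_y=self.outcome_table["se"].to_numpy(),
            flags=pd.DataFrame({"variant_id": self.outcome_table["variant_id"],
                                "status": "aligned"}),
        )


@dataclass
class CohortData:
    """Individual-level fixture for the genetic-risk-score analysis."""

    table: pd.DataFrame  # columns: individual_id, age, sex, phenotype, rs...
    variant_ids: list[str]
    truth: dict = field(default_factory=dict)


def _correlation_matrix(k: int, rho: float) -> np.ndarray:
    r = np.full((k, k), rho)
    np.fill_diagonal(r, 1.0)
    return r


def simulate_summary_pair(config: SimulationConfig) -> SummaryPair:
    """Generate exposure and outcome summary tables plus a truth record.

    The truth record retains the per-variant true effects ``gamma_<exposure>``,
    the pleiotropy term ``alpha`` and the corruption flags, with the causal
    ``true_effects`` echoed in ``truth.attrs``.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.exposures)
    j = config.n_variants
    theta = np.asarray(config.true_effects, float)

    variant_ids = np.array([f"rs{i + 1:07d}" for i in range(j)])
    block_of = np.repeat(np.arange(k), config.n_instruments)

    # true per-variant exposure effects, correlated across exposures
    corr = _correlation_matrix(k, config.exposure_correlation)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    gamma = (rng.standard_normal((j, k)) @ chol.T) * config.effect_sd
    if config.orient_instruments:
        primary = gamma[np.arange(j), block_of]
        flip = np.where(primary < 0, -1.0, 1.0)
        gamma *= flip[:, None]

    # allele frequencies and codings
    is_palindromic = rng.random(j) < config.frac_palindromic
    lo, hi = config.eaf_range
    eaf = rng.uniform(lo, hi, size=j)
    if config.ambiguous_palindromic:
        eaf[is_palindromic] = rng.uniform(0.42, 0.58, size=int(is_palindromic.sum()))
    else:
        # keep palindromic EAFs resolvable by the frequency rule
        n_pal = int(is_palindromic.sum())
        side = rng.random(n_pal) < 0.5
        eaf[is_palindromic] = np.where(
            side,
            rng.uniform(lo, min(0.40, hi), size=n_pal),
            rng.uniform(max(0.60, lo), hi, size=n_pal),
        )
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=j)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
    ea = np.empty(j, dtype="<U1")
    oa = np.empty(j, dtype="<U1")
    for i in range(j):
        pair = _PALINDROMIC_PAIRS[pal_idx[i]] if is_palindromic[i] else _NONPALINDROMIC_PAIRS[pair_idx[i]]
        ea[i], oa[i] = pair

    # pleiotropy
    if config.pleiotropy == "none":
        alpha = np.zeros(j)
    else:
        mean = config.pleiotropy_mean if config.pleiotropy == "directional" else 0.0
        alpha = rng.normal(mean, config.pleiotropy_sd, size=j)

    het = 2.0 * eaf * (1.0 - eaf)
    se_x = 1.0 / np.sqrt(het * config.n_exposure_sample)
    se_y = 1.0 / np.sqrt(het * config.n_outcome_sample)

    beta_x = gamma + config.noise_scale * se_x[:, None] * rng.standard_normal((j, k))
    beta_y_true = gamma @ theta + alpha
    beta_y = beta_y_true + config.noise_scale * se_y * rng.standard_normal(j)

    # outcome-table allele corruption
    corrupted = rng.random(j) < config.frac_allele_swapped
    out_ea, out_oa = ea.copy(), oa.copy()
    out_beta, out_eaf = beta_y.copy(), eaf.copy()
    swap = corrupted & ~is_palindromic
    out_ea[swap], out_oa[swap] = oa[swap], ea[swap]
    out_beta[swap] *= -1.0
    out_eaf[swap] = 1.0 - out_eaf[swap]
    strand = corrupted & is_palindromic  # strand flip: labels swap, effect unchanged
    out_ea[strand], out_oa[strand] = oa[strand], ea[strand]

    def _table(ids, ea_, oa_, eaf_, beta_, se_, n_) -> pd.DataFrame:
        pval = 2 * stats.norm.sf(np.abs(beta_ / se_))
        pval = np.maximum(pval, np.finfo(float).tiny)
        return pd.DataFrame({
            "variant_id": ids, "effect_allele": ea_, "other_allele": oa_,
            "eaf": eaf_, "beta": beta_, "se": se_, "pval": pval, "n": n_,
        })[SUMMARY_COLUMNS]

    exposure_tables = {
        name: _table(variant_ids, ea, oa, eaf, beta_x[:, ki], se_x,
                     config.n_exposure_sample)
        for ki, name in enumerate(config.exposures)
    }
    outcome_table = _table(variant_ids, out_ea, out_oa, out_eaf, out_beta, se_y,
                           config.n_outcome_sample)

    truth = pd.DataFrame({"variant_id": variant_ids,
                          "assigned_exposure": [config.exposures[b] for b in block_of],
                          "eaf": eaf, "alpha": alpha,
                          "beta_y_true": beta_y_true,
                          "palindromic": is_palindromic,
                          "corrupted": corrupted})
    for ki, name in enumerate(config.exposures):
        truth[f"gamma_{name}"] = gamma[:, ki]
    truth.attrs["true_effects"] = dict(zip(config.exposures, theta.tolist()))
    truth.attrs["seed"] = config.seed

    ld_table = _ld_table(variant_ids, config.ld_blocks)
    if not ld_table.empty:
        blocks = np.full(j, -1)
        pos = 0
        for bi, (size, _) in enumerate(config.ld_blocks or ()):
            blocks[pos:pos + size] = bi
            pos += size
        truth["ld_block"] = blocks

    return SummaryPair(exposure_tables, outcome_table, truth, ld_table, config)


def _ld_table(variant_ids: np.ndarray, blocks) -> pd.DataFrame:
    rows = []
    pos = 0
    for size, r2 in blocks or ():
        members = variant_ids[pos:pos + size]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                rows.append((members[a], members[b], r2))
        pos += size
    return pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"])


def simulate_cohort(
    config: SimulationConfig,
    grs_weights: pd.DataFrame,
    *,
    n_individuals: int = 5_000,
    grs_effect: float = 0.0,
    noise_sd: float = 1.0,
    age_effect: float = 0.0,
    sex_effect: float = 0.0,
) -> CohortData:
    """Simulate an age/sex-covaried cohort with genotype dosages in {0, 1, 2}.

    ``grs_weights`` needs columns ``variant_id``, ``eaf`` and ``weight``.
    The phenotype is ``grs_effect`` times the within-cohort standardized true
    weighted score, plus covariate effects and N(0, noise_sd) noise.
    """
    required = {"variant_id", "eaf", "weight"}
    if not required.issubset(grs_weights.columns):
        raise ValueError(f"grs_weights must have columns {sorted(required)}")
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    rng = np.random.default_rng(config.seed + 104729)  # offset: independent of GWAS draw
    ids = grs_weights["variant_id"].astype(str).to_numpy()
    freqs = grs_weights["eaf"].to_numpy(float)
    weights = grs_weights["weight"].to_numpy(float)
    if not np.all(np.isfinite(weights)):
        raise ValueError("GRS weights must be finite")

    dosage = rng.binomial(2, freqs[None, :], size=(n_individuals, len(ids))).astype(np.int8)
    score = dosage @ weights
    sd = score.std(ddof=0)
    std_score = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)

    age = rng.uniform(8.9, 11.5, size=n_individuals)
    sex = rng.integers(0, 2, size=n_individuals)
    phenotype = (grs_effect * std_score
                 + age_effect * (age - age.mean())
                 + sex_effect * sex
                 + rng.normal(0.0, noise_sd, size=n_individuals))

    table = pd.DataFrame({"individual_id": np.arange(1, n_individuals + 1),
                          "age": age, "sex": sex, "phenotype": phenotype})
    geno = pd.DataFrame(dosage, columns=ids, index=table.index)
    table = pd.concat([table, geno], axis=1)
    truth = {"grs_effect": grs_effect, "noise_sd": noise_sd,
             "age_effect": age_effect, "sex_effect": sex_effect,
             "seed": config.seed}
    return CohortData(table=table, variant_ids=list(ids), truth=truth)
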