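"""Configuration-driven orchestration of the full analysis graph:
instrument selection -> harmonisation -> clumping -> univariable estimators ->
multivariable models -> effect decomposition -> reverse-direction score
regression -> FDR -> intervention model, with tidy TSV outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import downstream, estimators, mvmr as mv
from . import harmonization as hz
from .io import read_cohort, read_ld_table, read_summary_stats, write_table

logger = logging.getLogger(__name__)

ESTIMATE_COLUMNS = [
    "exposure", "outcome", "method", "n_snps", "beta", "se", "ci_low",
    "ci_high", "pval", "or", "or_lcl", "or_ucl", "egger_intercept",
    "egger_intercept_se", "egger_intercept_pval", "Q", "Q_df", "Q_pval", "I2",
]


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a YAML mapping")
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _estimate_row(est) -> dict:
    d = est.to_dict()
    return {
        "exposure": d["exposure"], "outcome": d["outcome"], "method": d["method"],
        "n_snps": d["n_snps"], "beta": d["theta"], "se": d["se"],
        "ci_low": d["ci_low"], "ci_high": d["ci_high"], "pval": d["pval"],
        "or": d["or"], "or_lcl": d["or_lcl"], "or_ucl": d["or_ucl"],
        "egger_intercept": d["intercept"], "egger_intercept_se": d["se_intercept"],
        "egger_intercept_pval": d["pval_intercept"],
        "Q": d["Q"], "Q_df": d["Q_df"], "Q_pval": d["Q_pval"], "I2": d["I2"],
    }


def make_forest_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: one row per exposure x outcome x method with the OR,
    its CI and a fill flag set when the CI strictly excludes the null (1)."""
    if estimates.empty:
        raise ValueError("empty estimate table")
    forest = estimates[["exposure", "outcome", "method", "n_snps",
                        "or", "or_lcl", "or_ucl", "pval"]].copy()
    forest["fill"] = (forest["or_lcl"] > 1.0) | (forest["or_ucl"] < 1.0)
    return forest


def run_pipeline(config: dict, out_dir) -> dict[str, Path]:
    """Execute the configured analysis graph; returns written file paths.

    Reruns with an identical config (and therefore seed) are byte-identical.
    Every table carries the config hash and seed in a comment header.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config.get("seed", 0))
    meta = f"lifemr config_hash={chash} seed={seed}"
    analyses = config.get("analyses", {})
    thresholds = config.get("thresholds", {})
    p_thr = float(thresholds.get("instrument_pval", hz.DEFAULT_INSTRUMENT_P))
    r2_thr = float(thresholds.get("clump_r2", hz.DEFAULT_CLUMP_R2))
    band = tuple(thresholds.get("eaf_band", hz.DEFAULT_EAF_BAND))
    fdr_q = float(thresholds.get("fdr_q", 0.05))
    est_cfg = config.get("estimators", {})
    effects_model = est_cfg.get("effects_model", "multiplicative_random")
    n_boot = int(est_cfg.get("n_boot", 1000))

    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        write_table(df, path, header_comment=meta)
        paths[name] = path

    # ---- load inputs -------------------------------------------------
    stage = "load"
    exposure_paths = _require(config, "exposures")
    outcome_paths = _require(config, "outcomes")
    try:
        exposures = {label: read_summary_stats(p, name=label)
                     for label, p in exposure_paths.items()}
        outcomes = {label: read_summary_stats(p, name=label)
                    for label, p in outcome_paths.items()}
        ld_path = config.get("ld_reference")
        ld = read_ld_table(ld_path) if ld_path else pd.DataFrame(
            columns=["variant_a", "variant_b", "r2"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    if len({*exposures} & {*outcomes}):
        raise PipelineError(stage, "exposure and outcome labels must be unique")

    # ---- instrument selection and clumping ---------------------------
    stage = "clump"
    try:
        candidates = {label: hz.select_instruments(tab, p_thr)
                      for label, tab in exposures.items()}
        instruments = {}
        audit_rows = []
        for label, cand in candidates.items():
            retained = hz.clump(cand, ld, r2_thr)
            hz.assert_independent(retained, ld, r2_thr)
            instruments[label] = retained
            audit_rows.append({"exposure": label, "candidates": len(cand),
                               "retained": len(retained)})
            logger.info("%s: %d candidates, %d retained after clumping",
                        label, len(cand), len(retained))
        joint_instruments = hz.clump_multi(candidates, ld, r2_thr)
        hz.assert_independent(joint_instruments, ld, r2_thr)
        _write("instrument_counts", pd.DataFrame(audit_rows))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- univariable estimation --------------------------------------
    uni_rows, audit_flags = [], []
    harmonized: dict[tuple[str, str], hz.HarmonizedDataset] = {}
    if analyses.get("univariable", True):
        stage = "univariable"
        try:
            for olabel, otab in outcomes.items():
                for elabel, etab in exposures.items():
                    esel = etab[etab["variant_id"].isin(instruments[elabel])]
                    ds = hz.harmonize(esel, otab, eaf_ambiguity_band=band,
                                      exposure_label=elabel)
                    harmonized[(elabel, olabel)] = ds
                    audit_flags.append(ds.flags.assign(exposure=elabel, outcome=olabel))
                    labels = dict(exposure=elabel, outcome=olabel)
                    uni_rows.append(_estimate_row(
                        estimators.ivw(ds, effects_model=effects_model, **labels)))
                    if ds.n_variants >= 3:
                        uni_rows.append(_estimate_row(estimators.egger(ds, **labels)))
                        uni_rows.append(_estimate_row(estimators.weighted_median(
                            ds, n_boot=n_boot, seed=seed, **labels)))
            uni = pd.DataFrame(uni_rows, columns=ESTIMATE_COLUMNS)
            _write("estimates_univariable", uni)
            _write("forest_univariable", make_forest_table(uni))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # ---- multivariable estimation and decomposition ------------------
    mv_rows, decomp_rows = [], []
    if analyses.get("multivariable", True) and len(exposures) >= 2:
        stage = "multivariable"
        try:
            focal = config.get("mvmr", {}).get("focal_exposure",
                                               next(iter(exposures)))
            for olabel, otab in outcomes.items():
                per_exposure = {}
                for elabel, etab in exposures.items():
                    esel = etab[etab["variant_id"].isin(joint_instruments)]
                    per_exposure[elabel] = hz.harmonize(
                        esel, otab, eaf_ambiguity_band=band, exposure_label=elabel)
                ds = hz.merge_exposures(per_exposure, joint_instruments)
                model_ivw = mv.mvmr_ivw(ds, outcome=olabel)
                model_egger = mv.mvmr_egger(ds, focal_exposure=focal, outcome=olabel)
                for elabel in exposures:
                    mv_rows.append(_estimate_row(model_ivw[elabel]))
                    mv_rows.append(_estimate_row(model_egger[elabel]))
                    if (elabel, olabel) in harmonized:
                        total = estimators.ivw(harmonized[(elabel, olabel)],
                                               effects_model=effects_model,
                                               exposure=None)
                        total.exposure, total.outcome = elabel, olabel
                        dec = mv.decompose_effects(total, model_ivw[elabel])
                        decomp_rows.append(vars(dec))
            mv_df = pd.DataFrame(mv_rows, columns=ESTIMATE_COLUMNS)
            _write("estimates_multivariable", mv_df)
            _write("forest_multivariable", make_forest_table(mv_df))
            if decomp_rows:
                _write("decomposition", pd.DataFrame(decomp_rows))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        # FDR over the multivariable panel
        stage = "fdr"
        try:
            if mv_rows:
                family = pd.DataFrame(mv_rows)
                family = family[family["method"] == "mvmr_ivw"].reset_index(drop=True)
                adj = downstream.bh_fdr(family["pval"], q=fdr_q)
                fdr_table = pd.concat(
                    [family[["exposure", "outcome", "method"]], adj], axis=1)
                _write("fdr", fdr_table)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # ---- reverse direction (GRS) -------------------------------------
    if analyses.get("reverse", False):
        stage = "reverse"
        try:
            rcfg = _require(config, "reverse")
            cohort = read_cohort(rcfg["cohort"])
            weights = pd.read_csv(rcfg["instruments"], sep="\t", comment="#")
            instruments_set = downstream.InstrumentSet.from_frame(weights)
            res = downstream.grs_regression(
                cohort, instruments_set,
                covariates=tuple(rcfg.get("covariates", ("age", "sex"))),
                phenotype=rcfg.get("phenotype", "phenotype"))
            _write("reverse_grs", pd.DataFrame([{
                "beta_per_sd": res.beta, "se": res.se, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "pval": res.pval, "n": res.n,
                "covariates": ",".join(res.covariates)}]))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # ---- intervention model ------------------------------------------
    if analyses.get("intervention", False):
        stage = "intervention"
        try:
            icfg = _require(config, "intervention")
            scenario = downstream.InterventionScenario(
                category_proportions=tuple(icfg["category_proportions"]),
                rr_per_category=float(icfg["rr_per_category"]),
                baseline_prevalence=float(icfg["baseline_prevalence"]),
                shift=float(icfg["shift"]),
                category_labels=tuple(icfg["category_labels"])
                if "category_labels" in icfg else None)
            res = downstream.intervention_model(scenario)
            _write("intervention", pd.DataFrame([{
                "baseline_prevalence": res.baseline_prevalence,
                "post_prevalence": res.post_prevalence,
                "post_prevalence_pct_rounded": res.post_prevalence_pct_rounded,
                "percent_reduction": res.percent_reduction,
                "percent_reduction_from_rounded": res.percent_reduction_from_rounded,
            }]))
            _write("intervention_categories", res.proportion_table)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    if audit_flags:
        _write("harmonization_audit", pd.concat(audit_flags, ignore_index=True))
    meta_path = out_dir / "run_meta.json"
    meta_path.write_text(json.dumps(
        {"config_hash": chash, "seed": seed, "outputs": sorted(paths)},
        indent=2, sort_keys=True) + "\n")
    paths["run_meta"] = meta_path
    return paths


def _require(config: dict, key: str):
    if key not in config or config[key] in (None, {}):
        raise ConfigError(f"config section {key!r} is required")
    return config[key]
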