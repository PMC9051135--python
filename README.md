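# lifemr

Lifecourse two-sample Mendelian randomization (MR) toolkit: from raw GWAS
summary statistics through allele harmonisation and LD clumping to
univariable and multivariable causal-effect estimation, reverse-direction
genetic-risk-score analysis, false-discovery-rate control across a disease
panel, and a category-shift intervention prevalence model. A synthetic-data
generator reproduces the statistical structure of two-sample GWAS inputs so
the entire pipeline is testable without external data.

## Modules

| module | contents |
| --- | --- |
| `lifemr.simulate` | `SimulationConfig`, `simulate_summary_pair`, `simulate_cohort` — summary-level GWAS generator with configurable causal effects, between-exposure correlation, pleiotropy regimes, allele-coding corruption, block LD, and an individual-level cohort for score analyses |
| `lifemr.io` | TSV readers/writers for summary statistics (`variant_id, effect_allele, other_allele, eaf, beta, se, pval, n`), LD references (`variant_a, variant_b, r2`) and cohorts |
| `lifemr.harmonization` | `harmonize` (effect-allele alignment, strand resolution, palindromic EAF rule), `clump` / `clump_multi` (greedy p-value-ordered LD clumping, aggregated multi-exposure mode) |
| `lifemr.estimators` | `wald_ratio`, `ivw` (fixed / multiplicative random effects), `egger` (slope + pleiotropy intercept test), `weighted_median` (bootstrap SE), `heterogeneity` (Q, I²) |
| `lifemr.mvmr` | `mvmr_ivw`, `mvmr_egger` (direct effects of K simultaneous exposures), `decompose_effects` (total/direct/indirect with direct-vs-mediated classification) |
| `lifemr.downstream` | `grs_regression` (standardized weighted allele score + covariates), `bh_fdr` (Benjamini–Hochberg step-up), `intervention_model` (constant-RR category-shift prevalence model) |
| `lifemr.pipeline` / `lifemr.cli` | YAML-configured end-to-end orchestration with deterministic, hash-stamped TSV outputs and forest-plot tables |

## Command line

```bash
# generate a synthetic dataset (two exposures, outcome, truth record, LD table)
lifemr simulate --seed 7 --out-dir demo/ --cohort

# full pipeline from a YAML config
lifemr run --config config.yaml --out-dir results/

# individual stages
lifemr harmonize --exposure demo/exposure_childhood.tsv --outcome demo/outcome.tsv --out h.tsv
lifemr clump --candidates demo/exposure_childhood.tsv --ld demo/ld.tsv --out kept.tsv
lifemr mr --exposure demo/exposure_childhood.tsv --outcome demo/outcome.tsv --out mr.tsv
lifemr mvmr --exposure childhood demo/exposure_childhood.tsv \
            --exposure adult demo/exposure_adult.tsv \
            --outcome demo/outcome.tsv --out mvmr.tsv
lifemr reverse --cohort demo/cohort.tsv --instruments demo/grs_weights.tsv --out grs.tsv
lifemr fdr --pvals pvals.tsv --out fdr.tsv
lifemr intervene --proportions 0.33,0.511,0.159 --rr 2.64 --prevalence 0.005 --shift 0.10
```

A minimal `config.yaml` for `lifemr run`:

```yaml
seed: 7
exposures: {childhood: demo/exposure_childhood.tsv, adult: demo/exposure_adult.tsv}
outcomes: {t1d: demo/outcome.tsv}
ld_reference: demo/ld.tsv
thresholds: {instrument_pval: 5.0e-8, clump_r2: 0.001, eaf_band: [0.42, 0.58], fdr_q: 0.05}
estimators: {effects_model: multiplicative_random, n_boot: 1000}
analyses: {univariable: true, multivariable: true, reverse: false, intervention: true}
mvmr: {focal_exposure: childhood}
intervention: {category_proportions: [0.33, 0.511, 0.159], rr_per_category: 2.64,
               baseline_prevalence: 0.005, shift: 0.10}
```

Reruns with an identical config are byte-identical; every output table
carries the config hash and seed in a `#` comment header.

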