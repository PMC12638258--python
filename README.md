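# metaphenome

Analysis toolkit for plasma metabolome–phenome studies: metabolite QC and
transforms, phenome-wide association scans with multiplicity control,
nested case–control screening of pre-onset metabolite divergence,
sliding-window ageing-wave quantification, and calibrated boosted-tree
metabolic risk scores — together with a synthetic cohort generator that
plants known ground truth so every stage can be validated end to end.

## Modules

| Module | Role |
| --- | --- |
| `metaphenome.synthcohort` | Synthetic cohorts: block-correlated log-normal metabolite panel, covariates, disease registries (hazard-driven / divergence-driven / null), traits, planted age waves; all parameters recorded as ground truth |
| `metaphenome.preprocess` | 4×IQR outlier masking on the raw scale, natural-log + z transform, within-sex mode/median covariate imputation, pairwise Spearman correlations |
| `metaphenome.assocscan` | Marginal metabolite scans: logistic (prevalent), Cox/Efron (incident), OLS on inverse-normal traits, reversed OLS for binary traits, proportional-odds for ordinal traits; Bonferroni flags, sex/age subgroups, interactions, BH replication |
| `metaphenome.preonset` | Propensity-score nearest-neighbour matching (1:5, without replacement), per-timeframe case–control z/p profiles over 15 one-year bins, backward screening for the emergence bin, Ward/silhouette trajectory clustering |
| `metaphenome.ageingwaves` | Covariate-adjusted LOESS age curves, curve clustering, sliding-window low/high age-parcel regressions with per-centre BH, count series and crest-age peak detection |
| `metaphenome.metrs` | Geography-blocked 10-fold CV, gain-ranked top-30 metabolite panels, tuned + isotonic-calibrated histogram gradient boosting, bootstrap AUC CIs, DeLong comparisons, exact tree-path attribution |
| `metaphenome.pipeline` | Orchestration, YAML config with strict validation, TSV/Parquet I/O, checksummed run manifests, CLI |

## CLI

```bash
# generate a synthetic cohort from a simulation config
metaphenome simulate --config sim.yaml --out cohort/ --seed 1

# run the full pipeline (simulate -> preprocess -> scan -> preonset -> ageing -> metrs)
metaphenome all --config pipeline.yaml --seed 1

# or re-run a single stage from on-disk artifacts of earlier stages
metaphenome scan --config pipeline.yaml
```

A pipeline config is a YAML rendering of `metaphenome.pipeline.PipelineConfig`
(see `PipelineConfig().to_yaml()` for a template). Unknown keys are
rejected; the resolved config, a run log, and a SHA-256 manifest of every
output file are written into the run directory.

Outputs are tab-separated text: `associations.tsv`, `matched_sets.tsv`,
`timeframe_profiles.tsv`, `emergence_calls.tsv`, `clusters.tsv`,
`age_curves.tsv`, `deswan_long.tsv`, `deswan_counts.tsv`, `peaks.json`,
`metrs_panels.tsv`, `metrs_eval.tsv`.

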