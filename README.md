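# pbsi

Person-based similarity index (PBSI) analysis of regional brain morphometry.

The PBSI quantifies how similar one person's regional morphometric profile
(e.g. 100 cortical thickness values) is to the profiles of the other members
of their diagnostic group: for each subject, Spearman rank correlations are
computed against every other group member and averaged (`n − 1`
coefficients). Lower scores mean greater inter-individual heterogeneity.
This package provides a complete, tested pipeline around that statistic:

- **`pbsi.synthetic`** — multi-site, multi-group synthetic cohort generator
  with group-specific dispersion multipliers, additive/multiplicative site
  effects, and optional coupling between structural deviation and symptom
  severity (so every downstream stage is testable without patient data).
- **`pbsi.io`** — CSV/TSV readers and writers enforcing canonical atlas
  ordering (100 cortical parcels + 14 subcortical volumes) and metadata
  completeness.
- **`pbsi.harmonization`** — parametric empirical-Bayes location/scale batch
  adjustment (ComBat) per measure class, protecting group status as the sole
  covariate.
- **`pbsi.core`** — tie-aware Spearman profile correlation, within-group raw
  PBSI, z-scoring, and the Cortical / Total composites.
- **`pbsi.groups`** — greedy age/sex matching, 1.5×IQR outlier exclusion,
  age/sex-adjusted regression, one-way ANOVA with Tukey–Kramer post-hoc
  tests, and a demographics table.
- **`pbsi.clinical`** — Pearson correlations between PBSI scores and seven
  clinical variables with Benjamini–Hochberg FDR control per score family.
- **`pbsi.pipeline`** — reproducible end-to-end orchestration with a config
  hash, per-stage logging, and a run manifest.

## CLI

```sh
pbsi simulate --preset paper-like --seed 17 --out data/
pbsi harmonize --in data/ --out harmonized/
pbsi score --in harmonized/ --out pbsi_scores.csv
pbsi compare --scores pbsi_scores.csv --meta data/subjects.csv --out group_differences.csv
pbsi correlate --scores pbsi_scores.csv --clinical data/clinical.csv --group recent --out clinical_correlations.csv
pbsi run --config run.yaml          # full pipeline from a YAML RunConfig
```

Input directory layout: `thickness.csv`, `area.csv`, `volume.csv`,
`subcortical.csv` (wide subject × region tables, `subject_id` first column),
`subjects.csv` (group/site/age/sex, sex as M/F) and `clinical.csv`
(PANSS subscales and total, GAF, FSIQ, MQ, illness duration,
olanzapine-equivalent antipsychotic dose; missing values allowed).

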