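# lipidpanel

Longitudinal lipidome–growth panel analysis toolkit. It implements, as a
tested and reusable pipeline, the stages of a cohort analysis linking an
infant plasma lipidome to growth faltering:

- **`lipidpanel.qc`** — four-rule feature quality control for raw
  lipidomics tables (mass accuracy ≤ 5 ppm, ≥ 5× blank ratio, ≤ 10% zero
  values, dilution-series *r* ≥ 0.9), with per-step attrition reporting.
- **`lipidpanel.network`** — signed weighted correlation network
  (`a_ij = ((1+s_ij)/2)^β`, default β = 18), scale-free fit diagnostic,
  topological-overlap dissimilarity, average-linkage module detection with
  a minimum module size, module eigenlipids via SVD, and the inter-module
  correlation network.
- **`lipidpanel.panel`** — fixed-effects (within) panel regressions with
  child-clustered standard errors, Benjamini–Hochberg FDR screening of
  per-lipid time trends, and consecutive-visit paired *t* tests.
- **`lipidpanel.lcmm`** — latent-class linear mixed models of growth
  trajectories (natural cubic spline basis at age quantiles, random
  intercept + slope, multi-restart ECM with monotone log-likelihood), and
  AIC selection of the number of classes.
- **`lipidpanel.pvar`** — panel vector autoregression estimated by first
  difference or forward-orthogonal-deviation GMM (optionally system GMM
  with a levels equation), Hansen overidentification test, Andrews–Lu
  moment selection criteria for the lag order, companion-matrix stability
  check, and extraction of the signed directed temporal network from
  significant lag-1 coefficients.
- **`lipidpanel.simulate`** — synthetic cohort generator with known ground
  truth (latent growth classes, lipid module structure, VAR(1) dynamics
  with child fixed effects, engineered QC violations) backing every stage
  with parameter-recovery tests.
- **`lipidpanel.pipeline` / `lipidpanel.cli`** — end-to-end orchestration
  from a YAML config with a run manifest; per-stage subcommands.

## CLI

```bash
lipidpanel simulate --n-children 200 --seed 1 --out cohort.csv
lipidpanel network  --cohort cohort.csv --beta 18 --min-size 10 --out-dir results
lipidpanel panel    --cohort cohort.csv --out-dir results
lipidpanel lcmm     --cohort cohort.csv --response laz --k-min 2 --k-max 4 --out-dir results
lipidpanel pvar     --cohort cohort.csv --transform fod --system --out-dir results
lipidpanel run      --config config.yaml
```

A minimal `config.yaml` for an end-to-end simulated run:

```yaml
output_dir: results
seed: 1
simulate:
  n_children: 200
  n_modules: 3
  lipids_per_module: 10
  dropout_prob: 0.1
network: {min_size: 10}
lcmm: {response: laz, k_range: [2, 3, 4]}
pvar: {transform: fod, system: true}
```

Cohort CSVs are long format with one row per (child, visit): columns
`child_id`, `sex`, `week`, `visit_index`, the growth z-scores
`waz`/`laz`/`wlz`, and any number of `lipid_*` feature columns.

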