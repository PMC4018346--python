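# snplasso

Candidate-gene case-control SNP association analysis as a tested,
reusable pipeline:

- **`synthetic_cohort`** — case-control cohort simulator: control
  genotypes under Hardy-Weinberg at configurable minor-allele
  frequencies, case genotypes by exponential tilting (exactly consistent
  with an additive logistic model), covariates with configurable
  disease log-odds, stage/grade subphenotypes and a p53 histoscore
  model. Ships a 184-SNP default panel (16 reference tagSNPs with
  published control genotype counts + null fillers) and reference
  cohort margins (1,058 cases / 1,138 controls).
- **`data_prep`** — PLINK-`.raw`-style and CSV genotype IO, cohort CSV
  IO, minor-allele frequency, Hardy-Weinberg screening in controls
  (report-only flag at p ≤ 1e-4), mode-of-inheritance encodings
  (additive / dominant / recessive / codominant), frequency-sampling
  imputation of missing genotypes, histoscore + median-split p53
  classes, stage/grade → subphenotype mapping.
- **`single_snp_association`** — covariate-adjusted logistic
  likelihood-ratio tests per SNP under the four modes of inheritance,
  best-mode selection, polytomous subtype-heterogeneity LRTs, SNP×SNP
  and SNP×smoking interaction scans, min-p permutation correction for
  multiple testing, and analytic + simulated per-allele power.
- **`lasso_selection`** — L1-penalized logistic likelihood with
  unpenalized covariates (own IRLS + coordinate-descent solver with a
  KKT certificate on every fit), 5-fold cross-validated AIC penalty
  tuning, bootstrap stability selection (per-SNP reproducibility
  percentages), and permutation-corrected post-selection inference.
- **`cli_pipeline`** — orchestration (`simulate → prep → assoc → lasso
  → report`) behind a `snplasso` CLI with YAML config, per-stage seed
  substreams and a structured run log.

## CLI

```sh
# simulate a cohort and run the whole pipeline
snplasso all --seed 1 --out runs/demo -c config.yaml

# or stage by stage
snplasso simulate -c config.yaml
snplasso prep -c config.yaml
snplasso assoc -c config.yaml
snplasso lasso -c config.yaml
snplasso report -c config.yaml

# small deterministic test fixtures
snplasso make-fixtures --seed 0 --out fixtures
```

Example `config.yaml`:

```yaml
seed: 1
out_dir: runs/demo
simulate:
  n_cases: 1058
  n_controls: 1138
  n_snps: 184
  missing_rate: 0.01
  log_or_of: {rs6567355: 0.2}
assoc:
  n_perm: 1000
  family: lrt_additive
lasso:
  n_lambda: 50
  n_folds: 5
  n_bootstrap: 1000
  n_perm_post: 10000
```

Outputs per run directory: `genotypes.raw`, `cohort.csv`,
`snp_info.csv`, `genotypes_imputed.raw`, `snp_qc.csv`, `assoc.csv`
(per-SNP table with permutation-corrected p), `stability.json`
(λ path, reproducibility, post-selection test), `report.csv`, and
`run.log` (JSON lines with seeds, timings and all decision switches).

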