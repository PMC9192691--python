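# fxiselect

Discovery pipeline for plasma proteins associated with factor XI coagulant
activity (FXI:C) in a two-timepoint venous-thromboembolism cohort:
covariate-adjusted LASSO over a fractional-polynomial basis expansion of
every protein, lambda-ratio robustness ranking, prescribed sensitivity
analyses, correlation-augmented pathway over-representation, and
dense-subnetwork detection on protein–protein interaction graphs.

Because the motivating cohort data are access-restricted, the package ships
a first-class synthetic-data module that generates a structurally matched
cohort (correlated protein blocks, planted linear and nonlinear effects,
DOAC-shifted FXI:C, inversely related APTT, an FXI-antigen proxy with a
target Spearman correlation) so every stage can be exercised and tested
end to end with no downloads.

## Modules

| module                  | role |
|-------------------------|------|
| `fxiselect.synthetic`   | two-timepoint cohort + protein-matrix generator with a known planted truth; CSV/JSON fixtures |
| `fxiselect.preprocess`  | exclusions (active malignancy, FXI:C < 20%), |skew|-minimizing normality transforms, FXI:C strata (<70 / 70–150 / >150), descriptive table, paired t-test |
| `fxiselect.fp_lasso`    | FP basis expansion, unpenalized-covariate LASSO path (Frisch–Waugh–Lovell residualization), 10-fold CV-MSE lambda selection, entry-lambda tracking, lambda-ratio ranking, DOAC / APTT sensitivity analyses |
| `fxiselect.enrichment`  | GMT I/O, |Spearman rho| > 0.80 query augmentation, one-sided hypergeometric over-representation with measured-protein background |
| `fxiselect.network`     | edge-list graphs, Markov clustering (expansion/inflation), MCODE-style molecular complex detection, GO-style complex labelling |
| `fxiselect.pipeline`    | `run-all` orchestration with SHA-256 run manifest |

## CLI

```bash
fxiselect run-all --outdir out --seed 1            # full synthetic run
fxiselect simulate --outdir fixtures --seed 1
fxiselect fit --cohort fixtures/cohort.csv --proteins fixtures/proteins.csv \
    --timepoint acute --out acute.tsv --seed 1
fxiselect sensitivity-doac ...   # restricted to DOAC non-users
fxiselect sensitivity-aptt ...   # drops normal/high FXI:C with elongated APTT
fxiselect overlap --a acute.tsv --b followup.tsv
fxiselect enrich --query q.txt --gmt sets.gmt --background bg.txt --out enr.tsv
fxiselect network mcl|mcode|label ...
```

`run-all` writes fixtures, filtered cohort, per-timepoint selection tables
(protein, selected, direction, entry lambda, lambda ratio), sensitivity
tables, the shared/specific protein overlap, enrichment results and network
complexes under `--outdir`, plus `manifest.json` with per-file digests;
reruns with the same config and seed are byte-identical.

A YAML config can override any stage section (see
`fxiselect.pipeline.DEFAULT_CONFIG`), e.g.:

```yaml
seed: 1
simulate:
  n_acute: 549
  n_followup: 187
  n_proteins: 444
fit:
  k: 10
  n_lambdas: 100
sensitivity:
  aptt_threshold: 38.0
```

## Method notes

* Unpenalized covariates are implemented exactly by residualizing the
  outcome and the penalized features against the covariate span before the
  coordinate-descent path; covariate coefficients are recovered per lambda
  afterwards.
* The lambda grid spans `[eps * lambda_max, lambda_max]` with 100
  log-spaced points (`eps = 0.01`, the usual default when features
  outnumber samples). Entry-lambda detection is grid-based by default; a
  `refine_entry` option computes exact entry knots via LARS for small
  problems.
* Lambda-opt is the exact CV-MSE minimizer (not the 1-SE rule); folds are
  seeded and logged.
* Direction of (possibly nonlinear) associations is the sign of the
  marginal Spearman correlation between the raw protein and FXI:C.
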