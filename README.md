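# rdalert

Regression-discontinuity (RD) evaluation of threshold-triggered clinical
deterioration alerts, built as a tested, reusable pipeline:

- **`rdalert.synthetic_cohort`** — patient-level cohort generator with a
  known outcome-probability jump (`tau`) at a score threshold, a
  right-skewed (scaled Beta) running-variable distribution calibrated to a
  target above-threshold fraction, smooth-in-score covariates, optional
  treatment contamination (silent alerts / comfort care), trajectory-level
  simulation with event censoring, and score manipulation injection for
  density-test power studies.
- **`rdalert.rd_core`** — sharp-RD estimation: triangular/uniform-kernel
  local polynomial fits on each side of the threshold,
  heteroskedasticity-robust (HC1) normal-based inference, an MSE-optimal
  plug-in bandwidth selector in the Calonico–Cattaneo–Titiunik style, and
  bandwidth sensitivity sweeps.
- **`rdalert.density_diagnostics`** — threshold-anchored score histograms
  and the McCrary sorting test for running-variable manipulation.
- **`rdalert.falsification`** — covariate balance at the threshold, placebo
  analysis on unexposed cohorts, assignment-discontinuity verification, and
  an aggregated report with per-check verdicts.
- **`rdalert.pipeline`** / **`rdalert.cli`** — cohort CSV I/O with schema
  validation, binned outcome rates, the seven-row results table (manual /
  MSE-optimal / quadratic primary fits plus per-outcome optimal-bandwidth
  fits), figures, and deterministic machine-readable outputs.

Conventions: scores at exactly the threshold belong to the treated side;
kernel support is open at the bandwidth; binary-outcome effects are
reported in percentage points, covariates in native units.

## CLI

```bash
# generate a synthetic cohort with a -10.4 percentage-point jump at 65.0
rdalert generate --n 9896 --tau -0.104 --seed 1 --out cohort.csv

# full analysis (results table, sweeps, falsification report, figures)
rdalert analyze --seed 1 --out run_output
rdalert analyze --input cohort.csv --bandwidth 7 --out run_output

# falsification suite / bandwidth sweep on an existing cohort file
rdalert falsify --input cohort.csv
rdalert sweep --input cohort.csv --outcome primary
```

`rdalert analyze --config cfg.yaml` reads a YAML analysis config;
command-line flags override config-file values.

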