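# ckdflow

Longitudinal laboratory-data pipeline for **incident chronic kidney disease
(CKD) stage G3**: eGFR computation and KDIGO staging, acute-kidney-injury
(AKI) episode exclusion, incident-CKD case finding, rapid-progression and
alternative progression outcomes, and Aalen–Johansen competing-risk
estimation — driven by a synthetic registry generator with known ground
truth, so every stage is testable without access to real registry data.

## What it does

- **`ckdflow.egfr`** — CKD-EPI creatinine equations (2009, race coefficient
  not applied, and the race-free 2021 refit), GFR staging with the G3a/G3b
  split, and albuminuria staging (A1/A2/A3) from uACR.
- **`ckdflow.aki`** — KDIGO AKI onset detection on creatinine series
  (≥26.5 µmol/L rise within 48 h, or ≥1.5× the 7-day baseline), bounded
  episode construction, and exclusion flags for chronic phenotyping.
- **`ckdflow.phenotyping`** — incident CKD G3 case finding (two eGFR values
  in [30, 60) ≥90 days apart, with prevalent-disease lookback and prior-KRT
  exclusion), G3b substaging, and outcome detectors: confirmed and potential
  rapid progression (≥5 mL/min/1.73 m² drop + OLS slope ≤ −5/yr over the
  trailing year with ≥3 points spanning ≥90 days, confirmed 30–180 days
  later), drop in GFR category, kidney failure, hospitalization; competing
  death/censor coding.
- **`ckdflow.risks`** — Aalen–Johansen cause-specific cumulative incidence
  with Aalen-type variance and log(−log) confidence intervals, stratified
  estimation, the 1-/3-year risk-marker heat map
  (sex × albuminuria × diabetes × hypertension/CVD), and a Table-1-style
  cohort summary.
- **`ckdflow.simulate`** — synthetic registry generator: covariate
  marginals, progressor/non-progressor slope mixture with a logistic risk
  model, gamma-renewal visit process, lognormal measurement noise, AKI
  excursions, Gompertz/exponential death and exponential
  hospitalization/emigration; plus a closed-form inverse of the 2009
  equation and a constant-hazard competing-risks oracle.
- **`ckdflow.io` / `ckdflow.pipeline` / `ckdflow.cli`** — CSV interchange
  with schema validation and row-level error reporting, attrition
  accounting, a run manifest, and a CLI.

Times are numeric days since a configurable epoch; no calendar arithmetic.

## CLI

```sh
ckdflow simulate --n-persons 5000 --seed 1 --out-dir data/
ckdflow phenotype --measurements data/measurements.csv --persons data/persons.csv \
    --enrollment-start 1096 --enrollment-end 1826 --admin-end 3290 --out-dir out/
ckdflow estimate --outcomes out/outcomes.csv --outcome rapid --out out/curve.csv
ckdflow heatmap --outcomes out/outcomes.csv --persons data/persons.csv \
    --out out/heatmap.csv --figure out/heatmap.png
ckdflow summary --persons data/persons.csv --cohort out/cohort.csv --out out/summary.csv
ckdflow run ...                 # everything incl. manifest + attrition log
```

Every subcommand also accepts `--config config.yaml`; explicit flags win.
Exit codes: 0 ok, 2 config error, 3 data error, 1 internal.

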