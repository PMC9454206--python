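# crcvalid

External validation of colorectal-cancer (CRC) risk prediction models, as
a reusable, tested pipeline. The package is aimed at cancer
epidemiologists and biostatisticians who want to evaluate published risk
scores — point systems, logistic regressions, Cox models — on a
prospective cohort and ask the questions that matter for screening policy:
how well does each score discriminate future cases, how does it compare to
the age-based screening threshold in use today, how many cases does the
top risk decile capture, and are the published absolute risks calibrated
to the new population?

Because individual-level data from large population biobanks are
access-controlled, the package ships a synthetic cohort generator that
emulates the relevant structure of such a cohort — ages 30–79, ten urban
and rural regions, lifestyle and anthropometric covariates, an aspirin
variable observed only in the coronary-heart-disease subgroup, a rare CRC
outcome (~0.6% cumulative incidence over 10 years), competing death, loss
to follow-up, and administrative censoring at 10 years — with known ground
truth, so every stage of the pipeline runs and is testable end to end with
no data download.

## What it computes

- **Risk-score engine** (`crcvalid.registry`): declarative YAML model
  specs (nine shipped; the coefficient values are clearly-marked
  synthetic placeholders — see `src/crcvalid/registry/README.md`).
  Evaluation yields a linear predictor or point total per participant and,
  where the source article published one, an absolute risk:
  logistic `p = expit(β₀ + Σβx)`, Cox `p = 1 − S₀(t)^exp(Σβx)`, points →
  lookup table. Horizons are converted assuming an exponential event-time
  distribution: `r(t₂) = 1 − (1 − r(t₁))^(t₂/t₁)`.
- **Follow-up** (`crcvalid.followup`): exclusion rules (prior intestinal
  cancer, missing BMI) with an auditable log; outcome composites by
  literal ICD-10 ranges (CRC C18–C20, colon C18, rectal C19–C20,
  right-sided C18.0–C18.3, left-sided C18.5–C18.7); truncation at
  10 years, earliest event wins.
- **Discrimination** (`crcvalid.discrimination`): Mann–Whitney AUC with
  DeLong variance and paired DeLong tests; an age-≥56 screening
  comparator (for a binary marker, AUC = (sensitivity + specificity)/2);
  Harrell's C for the time-to-event sensitivity analysis; top-10%/25%
  screening sensitivity, specificity, PPV and NPV; subgroup analyses by
  sex, urbanicity and age group, plus site-specific outcomes.
- **Calibration** (`crcvalid.calibration`): observed (Kaplan–Meier
  complement) vs expected 10-year risk by deciles of expected risk, OLS
  calibration slope and intercept over the decile points, and affine
  recalibration `r' = slope·r + intercept`.
- **Pipeline** (`crcvalid.pipeline`, CLI `crcvalid`): orchestrates the
  whole validation deterministically and writes delimited report tables
  plus a run manifest.

## Worked example

```
python analysis/01_simulate_cohort.py --n 50000 --seed 1
python analysis/02_validate_models.py
```

prints (50,000 participants, 305 incident CRC cases = 0.61% over
10 years):

```
overall AUC (CRC), best to worst:
  hong           0.692 [0.661-0.722]
  imperiale      0.691 [0.661-0.721]
  ma_cox         0.686 [0.655-0.716]
  aleksandrova   0.680 [0.648-0.712]
  ma_point       0.674 [0.644-0.705]
  driver         0.672 [0.641-0.703]
  betes          0.663 [0.634-0.692]
  guo            0.642 [0.610-0.674]
  chen           0.636 [0.606-0.667]
age-56 comparator AUC: 0.618
7 models significantly beat the age threshold (two-sided DeLong, alpha 0.05)
best top-10% sensitivity: ma_cox 30.3%
```

Each AUC is the probability that a randomly chosen future case scores
above a randomly chosen non-case; the bracketed interval is a 95% DeLong
Wald CI. The age-56 comparator is the bare screening-age indicator — the
gap between it and the multivariable scores is the added value of
lifestyle information. The top-10% sensitivity says what fraction of all
future cases would be captured by inviting the highest-risk decile to
screening. `analysis/03_recalibrate.py` then reports per-model calibration
slopes (a slope below 1 means the model overestimates risk in this
population) and emits recalibrated risk tables;
`analysis/04_sensitivity.py` runs the C-statistic and aspirin-removal
sensitivity analyses.

With the shipped placeholder coefficients these numbers validate the
*machinery*, not the published models; transcribing the original
equations into the YAML specs is all that is needed to validate the real
scores.

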