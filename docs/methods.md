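# Methods

This note documents the models, estimators and design choices behind
`crcvalid`, in the spirit of the methods documentation of statsmodels or
lifelines: what is computed, under which assumptions, with which defaults,
and what the synthetic-data results do and do not show.

## Risk-score engine

A risk model is a declarative spec: a model type (`logistic`, `cox`,
`points`), a list of variables, and optionally a baseline risk. Each
variable maps one cohort column to a contribution:

- *continuous*: `coefficient · (scale·x + offset)` — the affine transform
  lets a spec re-centre or re-unit a covariate without touching the cohort
  schema (units are fixed at schema level: BMI kg/m², waist cm,
  physical activity MET-h/day);
- *binary*: `coefficient · 1{x}`;
- *categorical*: an exhaustive, mutually exclusive list of levels
  (`equals` / `in` / half-open numeric `range` conditions), exactly one of
  which is the reference with contribution 0.

Missing inputs are handled per variable by declared policy: contribute as
the reference level, exclude the record from that model, or impute a fixed
value. The aspirin variable in the two models that contain it defaults to
imputing non-use, because aspirin use is observed only in the
coronary-heart-disease subgroup; the pipeline's `drop_term` switch removes
the term entirely and the aspirin sensitivity analysis quantifies the
difference on identical records.

Absolute risk at the model's native horizon is `expit(lp)` for logistic
models (the linear predictor includes the intercept), `1 − S₀^exp(lp)` for
Cox models with a published baseline survival `S₀ ∈ (0,1)`, and a lookup
table from point-total strata for point scores. Models without a published
intercept, baseline survival, or risk table yield only a relative score —
in the shipped registry that is `chen`, `betes`, `aleksandrova` and
`ma_cox`, leaving five models with absolute risks, and only those five are
calibrated. The `ma_cox` spec is declared a Cox model (its source article
published both a point score and a Cox model) with no baseline survival.

Risks are moved between horizons assuming an exponential event-time
distribution, `r₂ = 1 − (1 − r₁)^(t₂/t₁)`; the `driver` model's native
20-year risks pass through this conversion to the 10-year scale before
calibration. The conversion is exactly invertible away from float
saturation (risks so close to 1 that `1 − r` underflows).

The shipped coefficient values are synthetic placeholders with plausible
epidemiological magnitudes; every engine behaviour is established on
synthetic specs in the test suite, so correctness is independent of
transcription. Variable structure (which covariates each model uses, its
type, horizon, and development sex) follows the original publications.

## Synthetic cohort generator

The generator emulates the structure the validation needs, with known
ground truth:

- **Covariates.** Age truncated-normal (mean 52, SD 10.5) on [30, 79];
  sex (59% female); 10 equiprobable regions, 5 urban and 5 rural;
  smoking, alcohol, BMI (normal 23.7 ± 3.3, floor 14), waist, height,
  diabetes (6%), gamma physical activity (mean 21 MET-h/day), diet
  frequency categories, education, marital status, NSAID use, metabolic
  syndrome, CHD history (3%), aspirin observed only given CHD (35%
  within), prior intestinal cancer (0.06%), and a 2×10⁻⁵ missing-BMI
  rate. These marginals are realistic order-of-magnitude choices for a
  middle-aged Chinese cohort, fixed once in `DEFAULT_MARGINALS`; the real
  cohort's tabulated values are not reproduced. Covariates are sampled
  independently given sex — the joint distribution is not emulated.
- **Outcomes.** CRC event times are exponential per record with hazard
  `λᵢ = λ₀·exp(lpᵢ)`, where `lp` is a configurable linear combination of
  design-matrix columns (defaults: age 0.075/yr, male 0.35, current
  smoking 0.30, ex-smoking 0.15, weekly alcohol 0.20, BMI 0.03/unit,
  diabetes 0.30, physical activity −0.015/MET-h·day⁻¹). λ₀ is calibrated
  by bracketed root finding so the expected fraction of CRC-first exits
  within 10 years, `E[λᵢ/(λᵢ+o)·(1−e^{−10(λᵢ+o)})]`, equals the target
  marginal incidence (default 0.58%, matching ~2976 cases per 512,415
  participants). Competing death (0.008/yr) and loss to follow-up
  (0.0009/yr) are independent exponentials with combined rate `o`;
  administrative censoring at 10 years; earliest process wins. CRC cases
  draw an ICD-10 site from a fixed split with C19–C20 at 48% of cases.
  The exponential-baseline choice matches the horizon-conversion
  assumption and keeps the incidence calibration closed-form.
- **Dates.** Integer days since epoch; event days are `ceil(t·365.25)`,
  so administrative exits land one day past 10 years and follow-up
  construction truncates them to exactly 10.0 years.
- **Determinism.** All sampling uses two children of
  `SeedSequence(seed)`; identical parameters give byte-identical CSVs.

What passing tests on this generator show: the engine, statistics and
pipeline are correct under a proportional-hazards world with independent
censoring and independent covariates. What they do not show: performance
of the real published models (placeholder coefficients), behaviour under
covariate correlation, regional incidence gradients, non-proportional
hazards, or informative censoring.

## Follow-up and outcomes

Exclusions (prior intestinal cancer; missing BMI) are applied before any
scoring, with a log that reports counts per rule and their overlap so the
retention arithmetic is exact even when rules overlap. Outcome composites
use literal ICD-10 ranges; C18.4 and C18.8/C18.9 count toward colon and
CRC but neither sided subset. Site-specific analyses censor — rather than
drop — CRC events at other sites at their event time, keeping risk sets
consistent with cohort-time logic. For binary ROC labels, an event within
10 years is a case and everyone else, including participants censored
early, is a control; the Cox C-statistic is the sensitivity analysis that
uses event timing instead.

## Discrimination

The AUC is the Mann–Whitney statistic with ties credited 0.5, computed
via midranks in O(n log n) and verified against exhaustive pair
enumeration. Variances and covariances use DeLong's structural
components: with case components `V₁₀` and control components `V₀₁`,
`var = S₁₀/m + S₀₁/n`. Confidence intervals are 95% Wald on the AUC
scale, truncated to [0, 1] (the CI method is a documented choice; DeLong
p-values are two-sided and reported unadjusted, with a Bonferroni column
for transparency). The paired test uses
`z = ΔAUC/√(var_a + var_b − 2·cov)`; identical score vectors define
`z = 0, p = 1`.

Harrell's C counts pairs where the earlier time is an observed event and
the comparator survives strictly longer; tied event times are unusable,
score ties score 0.5. Top-fraction screening metrics flag the
`⌈fraction·n⌉` highest scores — "the 10% with the highest risk" is read as
at-least-10% — with ties broken deterministically by (score descending,
participant id ascending). Subgroup strata lacking a case or a control are
reported as undefined with a reason rather than failing the run. Top-k
thresholds are computed on the whole cohort only, not re-derived within
subgroups.

## Calibration

Participants with defined absolute risk are split into deciles of
expected risk (ties share the lower group, so heavily tied point scores
collapse into fewer effective groups; the line is then fitted over the
non-empty group points). Observed risk per group defaults to the
Kaplan–Meier complement at 10 years — a crude proportion, also available
by switch, is biased downward when censoring precedes the horizon — and
the calibration line is OLS of observed on mean expected risk over group
points (group-point rather than individual-level regression). Slopes
below 1 indicate over-estimation. Recalibration applies
`r' = slope·r + intercept` and clamps to [0, 1] with clamping logged.
Refitting the line on the same data after recalibration returns slope 1
and intercept 0 up to rounding — an algebraic identity of OLS under an
affine transform of the regressor — which the tests use as a
self-consistency check.

## Pipeline

A full run is deterministic given (cohort, config, seed): fixed float
formatting, no timestamps in the manifest, and deterministic row order.
Sex-restricted models are evaluated in both sexes (the validation design
assesses every model separately in males and females even when developed
in males only); `applicable_sex` gates a warning at pipeline level, and an
exclusion only in the single-record engine API. A model whose required
column is missing from the cohort is carried through every report table as
undefined-with-reason; other models are unaffected. Report completeness is
enforced structurally: one row per configured (model × subgroup × outcome)
cell.

## Problem sizes and tolerances

The test suite exercises the statistics against oracles at n ≤ 200
(exact, 1e−12), and the stochastic recoveries at the analysis scale the
package targets: 100,000-participant cohorts for discrimination recovery
and the end-to-end run, 200,000 for calibration-slope recovery (a model
reporting 2× the true risk recovers slope ≈ 0.5 within three delta-method
standard errors), and 2,000 replicates for the DeLong null rejection
rate. Monte-Carlo bands are three standard errors throughout.

## Known limitations

- Calibration of the real published models requires transcribing their
  equations into the spec files; shipped values are placeholders.
- The generator's independent-covariate assumption understates the
  correlation structure of real lifestyle data (e.g. smoking–alcohol),
  so between-model AUC gaps on synthetic cohorts are narrower than on
  real data.
- With low loss to follow-up the C-statistic and the binary-outcome AUC
  differ by less than 0.002 here; cohorts with heavier early censoring
  will show larger gaps (and can reverse their sign).
- Flexible (spline) calibration curves and time-dependent ROC are out of
  scope; the calibration line is strictly affine.
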