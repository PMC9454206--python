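# Logistic model over a 20-year horizon, developed in men: age, BMI,
# smoking, alcohol. PLACEHOLDER coefficients (synthetic): structure only
# follows the original publication.
name: driver
model_type: logistic
native_horizon_years: 20
applicable_sex: male
intercept_or_baseline: -5.0
provenance: >
  Variable structure per the original article (logistic regression,
  20-year risk, male development cohort); coefficient values are
  placeholders (synthetic), not the published equation.
variables:
  - name: age
    source_column: age
    kind: categorical
    missing_policy: exclude_record
    levels:
      - {when: {range: [null, 50]}, contribution: 0.0, reference: true}
      - {when: {range: [50, 60]}, contribution: 0.55}
      - {when: {range: [60, 70]}, contribution: 1.05}
      - {when: {range: [70, null]}, contribution: 1.45}
  - name: bmi
    source_column: bmi
    kind: categorical
    missing_policy: exclude_record
    levels:
      - {when: {range: [null, 25]}, contribution: 0.0, reference: true}
      - {when: {range: [25, 30]}, contribution: 0.25}
      - {when: {range: [30, null]}, contribution: 0.45}
  - name: smoking
    source_column: smoking_status
    kind: categorical
    levels:
      - {when: {equals: never}, contribution: 0.0, reference: true}
      - {when: {equals: ex_regular}, contribution: 0.25}
      - {when: {equals: current}, contribution: 0.45}
  - name: alcohol
    source_column: alcohol_weekly
    kind: binary
    coefficient: 0.30
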