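# Logistic model with absolute risks, both sexes: age, sex, smoking,
# alcohol, aspirin use. Aspirin observed only in the CHD-history
# subgroup; default policy imputes non-use elsewhere. PLACEHOLDER
# coefficients (synthetic).
name: hong
model_type: logistic
native_horizon_years: 10
applicable_sex: both
intercept_or_baseline: -6.0
provenance: >
  Variable structure per the original article (logistic regression with
  published absolute risks); coefficients are placeholders (synthetic).
variables:
  - name: age
    source_column: age
    kind: continuous
    coefficient: 0.07
    missing_policy: exclude_record
  - name: sex
    source_column: sex
    kind: categorical
    levels:
      - {when: {equals: female}, contribution: 0.0, reference: true}
      - {when: {equals: male}, contribution: 0.35}
  - name: smoking
    source_column: smoking_status
    kind: categorical
    levels:
      - {when: {equals: never}, contribution: 0.0, reference: true}
      - {when: {equals: ex_regular}, contribution: 0.15}
      - {when: {equals: current}, contribution: 0.35}
  - name: alcohol
    source_column: alcohol_weekly
    kind: binary
    coefficient: 0.25
  - name: aspirin
    source_column: aspirin_use
    kind: binary
    coefficient: -0.25
    missing_policy: {impute_value: 0}
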