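# Logistic model with absolute risks, both sexes: age, sex, smoking,
# alcohol, physical activity, marriage, education, NSAID use, metabolic
# syndrome, red meat, aspirin use. Aspirin is observed only in the
# CHD-history subgroup; default policy imputes non-use elsewhere.
# PLACEHOLDER coefficients (synthetic).
name: imperiale
model_type: logistic
native_horizon_years: 10
applicable_sex: both
intercept_or_baseline: -6.2
provenance: >
  Variable structure per the original article (logistic regression with
  published absolute risks); coefficients are placeholders (synthetic).
variables:
  - name: age
    source_column: age
    kind: continuous
    coefficient: 0.065
    missing_policy: exclude_record
  - name: sex
    source_column: sex
    kind: categorical
    levels:
      - {when: {equals: female}, contribution: 0.0, reference: true}
      - {when: {equals: male}, contribution: 0.40}
  - name: smoking
    source_column: smoking_status
    kind: categorical
    levels:
      - {when: {equals: never}, contribution: 0.0, reference: true}
      - {when: {equals: ex_regular}, contribution: 0.20}
      - {when: {equals: current}, contribution: 0.40}
  - name: alcohol
    source_column: alcohol_weekly
    kind: binary
    coefficient: 0.20
  - name: physical_activity
    source_column: physical_activity
    kind: continuous
    coefficient: -0.012
  - name: marital_status
    source_column: marital_status
    kind: categorical
    levels:
      - {when: {equals: married}, contribution: 0.0, reference: true}
      - {when: {in: [widowed, other]}, contribution: 0.10}
  - name: education
    source_column: education
    kind: categorical
    levels:
      - {when: {equals: high_or_above}, contribution: 0.0, reference: true}
      - {when: {in: [no_formal, primary]}, contribution: 0.20}
      - {when: {equals: middle}, contribution: 0.10}
  - name: nsaid
    source_column: nsaid_use
    kind: binary
    coefficient: -0.20
  - name: metabolic_syndrome
    source_column: metabolic_syndrome
    kind: binary
    coefficient: 0.25
  - name: red_meat
    source_column: red_meat
    kind: categorical
    levels:
      - {when: {in: [rarely, monthly]}, contribution: 0.0, reference: true}
      - {when: {in: [weekly, daily]}, contribution: 0.20}
  - name: aspirin
    source_column: aspirin_use
    kind: binary
    coefficient: -0.30
    missing_policy: {impute_value: 0}
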