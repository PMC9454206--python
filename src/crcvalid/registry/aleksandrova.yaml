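# Logistic-form lifestyle score, both sexes: age, smoking, alcohol,
# physical activity, waist circumference, body height, vegetable, dairy,
# processed meat, sugar & confectionery. Published as a relative score
# without absolute risks (no intercept). PLACEHOLDER coefficients
# (synthetic).
name: aleksandrova
model_type: logistic
native_horizon_years: 10
applicable_sex: both
provenance: >
  Variable structure per the original article (lifestyle score without
  published absolute risks); coefficients are placeholders (synthetic).
variables:
  - name: age
    source_column: age
    kind: continuous
    coefficient: 0.06
    missing_policy: exclude_record
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
    coefficient: 0.20
  - name: physical_activity
    source_column: physical_activity
    kind: continuous
    coefficient: -0.012
  - name: waist
    source_column: waist_cm
    kind: continuous
    coefficient: 0.02
    transform: {scale: 1.0, offset: -80.0}
  - name: height
    source_column: height_cm
    kind: continuous
    coefficient: 0.01
    transform: {scale: 1.0, offset: -160.0}
  - name: vegetable
    source_column: vegetable
    kind: categorical
    levels:
      - {when: {equals: daily}, contribution: 0.0, reference: true}
      - {when: {in: [rarely, monthly, weekly]}, contribution: 0.15}
  - name: dairy
    source_column: dairy
    kind: categorical
    levels:
      - {when: {in: [weekly, daily]}, contribution: 0.0, reference: true}
      - {when: {in: [rarely, monthly]}, contribution: 0.10}
  - name: processed_meat
    source_column: processed_meat
    kind: categorical
    levels:
      - {when: {in: [rarely, monthly]}, contribution: 0.0, reference: true}
      - {when: {in: [weekly, daily]}, contribution: 0.15}
  - name: sugar_confectionery
    source_column: sugar_confectionery
    kind: categorical
    levels:
      - {when: {in: [rarely, monthly]}, contribution: 0.0, reference: true}
      - {when: {in: [weekly, daily]}, contribution: 0.10}
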