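# Point score, both sexes: age, sex, BMI. No published absolute risks.
# PLACEHOLDER points (synthetic).
name: betes
model_type: points
native_horizon_years: 10
applicable_sex: both
provenance: >
  Variable structure per the original article (point score over age, sex
  and BMI; no published absolute risks); values are placeholders (synthetic).
variables:
  - name: age
    source_column: age
    kind: categorical
    missing_policy: exclude_record
    levels:
      - {when: {range: [null, 50]}, contribution: 0, reference: true}
      - {when: {range: [50, 60]}, contribution: 1}
      - {when: {range: [60, 70]}, contribution: 2}
      - {when: {range: [70, null]}, contribution: 3}
  - name: sex
    source_column: sex
    kind: categorical
    levels:
      - {when: {equals: female}, contribution: 0, reference: true}
      - {when: {equals: male}, contribution: 1}
  - name: bmi
    source_column: bmi
    kind: categorical
    missing_policy: exclude_record
    levels:
      - {when: {range: [null, 25]}, contribution: 0, reference: true}
      - {when: {range: [25, null]}, contribution: 1}
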