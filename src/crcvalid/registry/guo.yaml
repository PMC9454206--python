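# Point score developed in Chinese men: age, alcohol, diabetes, waist
# circumference, occupational sitting time (proxied by the cohort's
# sitting-time category). PLACEHOLDER points and risk table (synthetic).
name: guo
model_type: points
native_horizon_years: 10
applicable_sex: male
provenance: >
  Variable structure per the original article (point score with published
  absolute risks; occupational sitting time mapped to the schema's
  sitting-time category); values are placeholders (synthetic).
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
  - name: alcohol
    source_column: alcohol_weekly
    kind: binary
    coefficient: 1
  - name: diabetes
    source_column: diabetes
    kind: binary
    coefficient: 1
  - name: waist
    source_column: waist_cm
    kind: categorical
    levels:
      - {when: {range: [null, 85]}, contribution: 0, reference: true}
      - {when: {range: [85, null]}, contribution: 1}
  - name: sitting_time
    source_column: sitting_time
    kind: categorical
    levels:
      - {when: {equals: low}, contribution: 0, reference: true}
      - {when: {equals: medium}, contribution: 1}
      - {when: {equals: high}, contribution: 2}
risk_table:
  - {min_points: 0, max_points: 1, risk: 0.002}
  - {min_points: 2, max_points: 3, risk: 0.004}
  - {min_points: 4, max_points: 5, risk: 0.007}
  - {min_points: 6, max_points: 8, risk: 0.012}
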