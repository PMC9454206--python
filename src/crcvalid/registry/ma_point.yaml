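# Integer point score with a published points-to-risk table, developed in
# men: age, BMI, smoking, alcohol, physical activity. PLACEHOLDER point
# values and risk table (synthetic).
name: ma_point
model_type: points
native_horizon_years: 10
applicable_sex: male
provenance: >
  Variable structure per the original article (point score with published
  absolute risks); point values and risk table are placeholders (synthetic).
variables:
  - name: age
    source_column: age
    kind: categorical
    missing_policy: exclude_record
    levels:
      - {when: {range: [null, 50]}, contribution: 0, reference: true}
      - {when: {range: [50, 60]}, contribution: 2}
      - {when: {range: [60, 70]}, contribution: 4}
      - {when: {range: [70, null]}, contribution: 5}
  - name: bmi
    source_column: bmi
    kind: categorical
    levels:
      - {when: {range: [null, 25]}, contribution: 0, reference: true}
      - {when: {range: [25, null]}, contribution: 1}
  - name: smoking
    source_column: smoking_status
    kind: categorical
    levels:
      - {when: {equals: never}, contribution: 0, reference: true}
      - {when: {equals: ex_regular}, contribution: 1}
      - {when: {equals: current}, contribution: 2}
  - name: alcohol
    source_column: alcohol_weekly
    kind: binary
    coefficient: 1
  - name: physical_activity
    source_column: physical_activity
    kind: categorical
    levels:
      - {when: {range: [20, null]}, contribution: 0, reference: true}
      - {when: {range: [null, 20]}, contribution: 1}
risk_table:
  - {min_points: 0, max_points: 2, risk: 0.001}
  - {min_points: 3, max_points: 4, risk: 0.002}
  - {min_points: 5, max_points: 6, risk: 0.004}
  - {min_points: 7, max_points: 8, risk: 0.008}
  - {min_points: 9, max_points: 10, risk: 0.013}
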