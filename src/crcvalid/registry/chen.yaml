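# Point score developed in a Chinese population, both sexes: age, sex,
# coronary-heart-disease history, egg intake, defecation frequency.
# No published absolute risks. PLACEHOLDER points (synthetic).
name: chen
model_type: points
native_horizon_years: 10
applicable_sex: both
provenance: >
  Variable structure per the original article (point score, no published
  absolute risks); point values are placeholders (synthetic).
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
  - name: chd_history
    source_column: chd_history
    kind: binary
    coefficient: 1
  - name: egg
    source_column: egg
    kind: categorical
    levels:
      - {when: {in: [rarely, monthly]}, contribution: 0, reference: true}
      - {when: {in: [weekly, daily]}, contribution: 1}
  - name: defecation_frequency
    source_column: defecation_frequency
    kind: categorical
    levels:
      - {when: {equals: daily}, contribution: 0, reference: true}
      - {when: {equals: more_than_daily}, contribution: 1}
      - {when: {equals: less_than_daily}, contribution: 1}
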