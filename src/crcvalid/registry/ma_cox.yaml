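# Cox model developed in men: age, BMI, smoking, alcohol, physical
# activity. No published baseline survival, so only the linear predictor
# (relative ranking) is defined — absolute 10-year risk is undefined.
# PLACEHOLDER coefficients (synthetic).
name: ma_cox
model_type: cox
native_horizon_years: 10
applicable_sex: male
provenance: >
  Variable structure per the original article (Cox model, companion to the
  point score); coefficients are placeholders (synthetic); no baseline
  survival published, hence no absolute risk.
variables:
  - name: age
    source_column: age
    kind: continuous
    coefficient: 0.07
    missing_policy: exclude_record
  - name: bmi
    source_column: bmi
    kind: continuous
    coefficient: 0.04
    missing_policy: exclude_record
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
    coefficient: 0.25
  - name: physical_activity
    source_column: physical_activity
    kind: continuous
    coefficient: -0.012
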