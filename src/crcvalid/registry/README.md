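# Shipped model registry

One YAML file per published colorectal-cancer risk model, in the dialect
documented in `crcvalid.registry`. The *structure* of each spec — model
type, native horizon, development sex, variable list, and whether the
source article published absolute risks — follows the original
publications. The *coefficient and point values are placeholders*
(synthetic, epidemiologically plausible magnitudes), because the published
equations are not transcribed into this repository; every engine behaviour
is tested on synthetic specs, so correctness never depends on these
numbers. To validate the real models, replace the placeholder values with
the published ones — the file format is designed so this is a transcription
job, not a code change.

| model        | type     | horizon | developed in | absolute risk |
|--------------|----------|---------|--------------|---------------|
| driver       | logistic | 20 y    | males        | yes           |
| ma_point     | points   | 10 y    | males        | yes (table)   |
| ma_cox       | cox      | 10 y    | males        | no            |
| guo          | points   | 10 y    | males        | yes (table)   |
| chen         | points   | 10 y    | both         | no            |
| betes        | points   | 10 y    | both         | no            |
| aleksandrova | logistic | 10 y    | both         | no            |
| imperiale    | logistic | 10 y    | both         | yes           |
| hong         | logistic | 10 y    | both         | yes           |
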