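# MAGGIC heart-failure integer point score, transcribed from the published
# meta-analysis risk model.  Bands are half-open [lo, hi); the age and
# systolic-BP point tables are conditional on the ejection-fraction band.
# Creatinine is scored in umol/L; `scale` converts from the cohort's mg/dL.
# Transcription by the package authors; verify against the original
# publication before any clinical use.
score: MAGGIC
components:
  - variable: lvef
    kind: bands
    bands:
      - [-.inf, 20, 7]
      - [20, 25, 6]
      - [25, 30, 5]
      - [30, 35, 3]
      - [35, 40, 2]
      - [40, .inf, 0]
  - variable: age
    kind: conditional_bands
    condition_variable: lvef
    cases:
      - condition_band: [-.inf, 30]
        bands:
          - [-.inf, 55, 0]
          - [55, 60, 1]
          - [60, 65, 2]
          - [65, 70, 4]
          - [70, 75, 6]
          - [75, 80, 8]
          - [80, .inf, 10]
      - condition_band: [30, 40]
        bands:
          - [-.inf, 55, 0]
          - [55, 60, 2]
          - [60, 65, 4]
          - [65, 70, 6]
          - [70, 75, 8]
          - [75, 80, 10]
          - [80, .inf, 13]
      - condition_band: [40, .inf]
        bands:
          - [-.inf, 55, 0]
          - [55, 60, 3]
          - [60, 65, 5]
          - [65, 70, 7]
          - [70, 75, 9]
          - [75, 80, 12]
          - [80, .inf, 15]
  - variable: systolic_bp
    kind: conditional_bands
    condition_variable: lvef
    cases:
      - condition_band: [-.inf, 30]
        bands:
          - [-.inf, 110, 5]
          - [110, 120, 4]
          - [120, 130, 3]
          - [130, 140, 2]
          - [140, 150, 1]
          - [150, .inf, 0]
      - condition_band: [30, 40]
        bands:
          - [-.inf, 110, 3]
          - [110, 120, 2]
          - [120, 130, 1]
          - [130, 140, 1]
          - [140, 150, 0]
          - [150, .inf, 0]
      - condition_band: [40, .inf]
        bands:
          - [-.inf, 110, 2]
          - [110, 120, 1]
          - [120, 130, 1]
          - [130, 140, 0]
          - [140, 150, 0]
          - [150, .inf, 0]
  - variable: bmi
    kind: bands
    bands:
      - [-.inf, 15, 6]
      - [15, 20, 5]
      - [20, 25, 3]
      - [25, 30, 2]
      - [30, .inf, 0]
  - variable: creatinine
    kind: bands
    scale: 88.4   # mg/dL -> umol/L
    bands:
      - [-.inf, 90, 0]
      - [90, 110, 1]
      - [110, 130, 2]
      - [130, 150, 3]
      - [150, 170, 4]
      - [170, 210, 5]
      - [210, 250, 6]
      - [250, .inf, 8]
  - variable: nyha
    kind: categories
    # generalized labels (I/II, III/IV) score the rounded midpoint of the
    # classes they merge, so anonymized tables stay scoreable
    points: {I: 0, II: 2, III: 6, IV: 8, I/II: 1, III/IV: 7}
  - variable: sex_male
    kind: boolean
    if_true: 1
  - variable: current_smoking
    kind: boolean
    if_true: 1
  - variable: diabetes
    kind: boolean
    if_true: 3
  - variable: chronic_lung_disease
    kind: boolean
    if_true: 2
  - variable: hf_duration_ge_18m
    kind: boolean
    if_true: 2
  - variable: beta_blocker
    kind: boolean
    if_false: 3
  - variable: acei_arb
    kind: boolean
    if_false: 1
# 1-year probability of death by integer score (clamped outside 0..50).
mortality_1y:
  0: 0.015
  1: 0.016
  2: 0.018
  3: 0.020
  4: 0.022
  5: 0.024
  6: 0.027
  7: 0.029
  8: 0.032
  9: 0.036
  10: 0.039
  11: 0.043
  12: 0.048
  13: 0.052
  14: 0.058
  15: 0.063
  16: 0.070
  17: 0.077
  18: 0.084
  19: 0.093
  20: 0.102
  21: 0.111
  22: 0.122
  23: 0.134
  24: 0.147
  25: 0.160
  26: 0.175
  27: 0.191
  28: 0.209
  29: 0.227
  30: 0.248
  31: 0.269
  32: 0.292
  33: 0.316
  34: 0.342
  35: 0.369
  36: 0.398
  37: 0.427
  38: 0.458
  39: 0.490
  40: 0.523
  41: 0.556
  42: 0.590
  43: 0.625
  44: 0.658
  45: 0.692
  46: 0.725
  47: 0.757
  48: 0.787
  49: 0.816
  50: 0.842
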