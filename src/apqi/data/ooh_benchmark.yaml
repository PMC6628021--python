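# Published summary counts from a two-year audit (July 2016 - June 2018) of
# antibiotic prescribing at five Flemish out-of-hours GP cooperatives.
# The record-level data behind these counts are not public; the counts serve
# two purposes here:
#   * calibration source for the default synthetic scenario, and
#   * worked-example fixtures that exercise the coverage arithmetic on
#     exactly these printed totals.
study:
  n_encounters: 111600          # consultations at the cooperatives, home visits excluded
  total_prescriptions: 26436    # systemic antibacterial (J01) prescriptions
  n_sites: 5
  period: [2016-07-01, 2018-06-30]
  site_populations:             # catchment populations of the five cooperatives
    GPC1: 148366
    GPC2: 141110
    GPC3: 185358
    GPC4: 84430
    GPC5: 251833

# Antibiotic prescriptions per ICPC-2 chapter ("missing" = prescription with
# no diagnosis registered in the same consultation).
chapter_counts:
  R: 11526
  U: 3448
  S: 3125
  H: 2839
  D: 1707
  missing: 1612
  other: 2179                   # chapters A, Y, L, X, B, F, W, K, P, N, T pooled

# Antibiotic prescriptions per indicator diagnosis.
indication_counts:
  R74: 3564
  U71: 3068
  R76: 2294
  R78: 2223
  H71: 2129
  S76: 1344
  D82: 982
  R75: 965
  R81: 684

# Pooled indicator values in percent (a, b, c) with the min-max brackets
# observed across the five individual cooperatives.
indicator_values:
  H71: {a: 64, b: 74, c: 1, bracket_a: [52, 71], bracket_b: [72, 81], bracket_c: [0, 1]}
  R74: {a: 30, b: 3,  c: 2, bracket_a: [15, 41], bracket_b: [2, 7],   bracket_c: [0, 2]}
  R75: {a: 51, b: 40, c: 7, bracket_a: [39, 57], bracket_b: [35, 51], bracket_c: [2, 9]}
  R76: {a: 77, b: 6,  c: 1, bracket_a: [65, 87], bracket_b: [3, 15],  bracket_c: [0, 1]}
  R78: {a: 69, b: 42, c: 11, bracket_a: [58, 75], bracket_b: [37, 54], bracket_c: [5, 15]}
  R81: {a: 80, b: 46, c: 15, bracket_a: [70, 85], bracket_b: [42, 62], bracket_c: [2, 20]}
  U71: {a: 91, b: 69, c: 25, bracket_a: [77, 95], bracket_b: [64, 77], bracket_c: [18, 32]}
  S76: {a: 80, b: 44, c: 1, bracket_a: [64, 83], bracket_b: [36, 59], bracket_c: [0, 2]}
  D82: {a: 67, b: 42, c: 1, bracket_a: [53, 72], bracket_b: [38, 52], bracket_c: [0, 2]}

# Share of all antibiotic prescriptions linked to a symptom diagnosis
# (complaint rubrics such as fever or cough), in percent.
symptom_prescription_share: 3.8
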