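# Default model inputs: two-stage PHQ screening + collaborative care for
# depression in primary care, constant 2015 USD throughout.
# Triangulars are [low, base (mode), high].
schema: 1
model:
  discount_rate: 0.03
  age_start: 20
  age_end: 70
  primary_care_multiplier: 1.74
  wtp_reference: 40000
  productivity_age_cap: null
  p_depression_scale: 1.0
  fn_fallback: true
  screen_positive_treatment_gate: true
  feedback_policy: incremental_remissions
utilities:
  depressed: 0.52
  remission: 0.76
  well: 1.0
costs:
  treatment_cc: 2879.0
  treatment_uc: 2016.0
  screening_two_stage: 5.0
  absenteeism: 609.0
  presenteeism: 1975.0
  wage_gp: 83.0
  wage_rn: 34.0
  minutes_gp_phq2: 1.0
  minutes_gp_phq9: 3.0
  minutes_rn: 6.0
probabilities:
  treatable: 0.67
  diagnosis_status_quo: 0.52
  treatment_if_diagnosed: 0.61
  adequate_cc: 0.75
  adequate_uc: 0.44
phq2:
  cutoff: 3
  sensitivity: 0.83
  specificity: 0.90
  alternates:
    2: [0.93, 0.74]
    4: [0.73, 0.93]
phq9:
  cutoff: 10
  sensitivity: 0.88
  specificity: 0.88
  alternates:
    9: [0.95, 0.84]
    11: [0.83, 0.89]
triangulars:
  u_depressed: [0.47, 0.52, 0.58]
  u_remission: [0.70, 0.76, 0.82]
  c_treatment_cc: [2159.0, 2879.0, 3599.0]
  c_treatment_uc: [1512.0, 2016.0, 2520.0]
  c_screening: [3.0, 5.0, 7.0]
  c_productivity_total: [0.0, 2584.0, 2584.0]
  p_treatable: [0.63, 0.67, 0.71]
  p_diagnosis_status_quo: [0.42, 0.52, 0.62]
  p_treatment_if_diagnosed: [0.48, 0.61, 0.74]
  p_adequate_cc: [0.67, 0.75, 0.83]
  p_adequate_uc: [0.35, 0.44, 0.53]
  se_phq2: [0.73, 0.83, 0.93]
  sp_phq2: [0.74, 0.90, 0.93]
  se_phq9: [0.83, 0.88, 0.95]
  sp_phq9: [0.84, 0.88, 0.89]
  p_depression_scale: [0.8, 1.0, 1.2]
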