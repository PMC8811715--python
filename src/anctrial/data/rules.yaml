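thresholds:
  anaemia:
    severe_below: 7.0
    moderate_below: 10.0
    mild_below: 11.0
  hypertension:
    mild:
      sbp: 140.0
      dbp: 90.0
    moderate:
      sbp: 150.0
      dbp: 100.0
    severe:
      sbp: 160.0
      dbp: 110.0
  glucose:
    rbs_positive_at: 140.0
    urine_acceptable_below_ga: 24
  growth:
    discrepancy: 2.0
rules:
- id: anaemia_mild_moderate
  condition: anaemia
  classes:
  - mild
  - moderate
  actions:
  - action: repeat_hb_4wk
    deadline_days: 28
- id: anaemia_severe
  condition: anaemia
  classes:
  - severe
  actions:
  - action: refer_hospital
    deadline_days: null
- id: htn_mild_gest
  condition: hypertension
  classes:
  - mild_gest
  actions:
  - action: repeat_bp_4d
    deadline_days: 4
- id: htn_moderate_severe_chronic
  condition: hypertension
  classes:
  - moderate_gest
  - severe_gest
  - chronic
  actions:
  - action: refer_high_risk_or_hospital
    deadline_days: null
- id: glucose_positive
  condition: diabetes
  classes:
  - positive
  actions:
  - action: refer_high_risk_or_hospital
    deadline_days: null
- id: growth_abnormal
  condition: growth
  classes:
  - abnormal
  actions:
  - action: ultrasound_1wk
    deadline_days: 7
  - action: refer_high_risk_or_hospital
    deadline_days: null
- id: malpresentation
  condition: malpresentation
  classes:
  - non_cephalic
  actions:
  - action: refer_hospital
    deadline_days: null
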