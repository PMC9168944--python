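instrument_id: eq5d3l
name: EuroQol 5-dimension 3-level
scoring_rule: per-dimension-rescale
higher_is_better: false
domains:
- domain_id: mobility
  name: Mobility
  raw_min: 1
  raw_max: 3
  items:
  - item_id: eq_mobility
    prompt: Mobility
    levels:
      min: 1
      max: 3
- domain_id: self_care
  name: Self-care
  raw_min: 1
  raw_max: 3
  items:
  - item_id: eq_self_care
    prompt: Self-care
    levels:
      min: 1
      max: 3
- domain_id: usual_activities
  name: Usual activities
  raw_min: 1
  raw_max: 3
  items:
  - item_id: eq_usual_activities
    prompt: Usual activities
    levels:
      min: 1
      max: 3
- domain_id: pain_discomfort
  name: Pain / discomfort
  raw_min: 1
  raw_max: 3
  items:
  - item_id: eq_pain_discomfort
    prompt: Pain / discomfort
    levels:
      min: 1
      max: 3
- domain_id: anxiety_depression
  name: Anxiety / depression
  raw_min: 1
  raw_max: 3
  items:
  - item_id: eq_anxiety_depression
    prompt: Anxiety / depression
    levels:
      min: 1
      max: 3
- domain_id: health_rating
  name: Health rating
  raw_min: 0
  raw_max: 100
  scoring_rule: passthrough-0-100
  higher_is_better: true
  items:
  - item_id: eq_vas
    prompt: Health rating today
    levels:
      min: 0
      max: 100
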