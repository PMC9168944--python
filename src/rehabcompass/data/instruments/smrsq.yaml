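instrument_id: smrsq
name: Simplified modified Rankin Scale questionnaire
scoring_rule: grade-rescale
higher_is_better: false
domains:
- domain_id: disability
  name: Global disability
  raw_min: 0
  raw_max: 5
  items:
  - item_id: smrsq5
    prompt: Needs constant care
    levels: &id001
    - code: 0
      label: 'no'
    - code: 1
      label: 'yes'
    grade: 5
  - item_id: smrsq4
    prompt: Needs help with eating, hygiene or walking
    levels: *id001
    grade: 4
  - item_id: smrsq3
    prompt: Needs help with household tasks or finances
    levels: *id001
    grade: 3
  - item_id: smrsq2
    prompt: Unable to do all previous activities
    levels: *id001
    grade: 2
  - item_id: smrsq1
    prompt: Has any residual symptoms
    levels: *id001
    grade: 1
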