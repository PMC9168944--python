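instrument_id: fas
name: Fatigue Assessment Scale
scoring_rule: sum-rescale
higher_is_better: false
domains:
- domain_id: fatigue
  name: Fatigue
  raw_min: 10
  raw_max: 50
  items:
  - item_id: fas1
    prompt: Fatigue item 1
    levels:
      min: 1
      max: 5
  - item_id: fas2
    prompt: Fatigue item 2
    levels:
      min: 1
      max: 5
  - item_id: fas3
    prompt: Fatigue item 3
    levels:
      min: 1
      max: 5
  - item_id: fas4
    prompt: Fatigue item 4
    levels:
      min: 1
      max: 5
  - item_id: fas5
    prompt: Fatigue item 5
    levels:
      min: 1
      max: 5
  - item_id: fas6
    prompt: Fatigue item 6
    levels:
      min: 1
      max: 5
  - item_id: fas7
    prompt: Fatigue item 7
    levels:
      min: 1
      max: 5
  - item_id: fas8
    prompt: Fatigue item 8
    levels:
      min: 1
      max: 5
  - item_id: fas9
    prompt: Fatigue item 9
    levels:
      min: 1
      max: 5
  - item_id: fas10
    prompt: Fatigue item 10
    levels:
      min: 1
      max: 5
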