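instrument_id: eat10
name: Eating Assessment Tool
scoring_rule: sum-rescale
higher_is_better: false
domains:
- domain_id: swallowing
  name: Swallowing
  raw_min: 0
  raw_max: 40
  items:
  - item_id: eat1
    prompt: Swallowing item 1
    levels:
      min: 0
      max: 4
  - item_id: eat2
    prompt: Swallowing item 2
    levels:
      min: 0
      max: 4
  - item_id: eat3
    prompt: Swallowing item 3
    levels:
      min: 0
      max: 4
  - item_id: eat4
    prompt: Swallowing item 4
    levels:
      min: 0
      max: 4
  - item_id: eat5
    prompt: Swallowing item 5
    levels:
      min: 0
      max: 4
  - item_id: eat6
    prompt: Swallowing item 6
    levels:
      min: 0
      max: 4
  - item_id: eat7
    prompt: Swallowing item 7
    levels:
      min: 0
      max: 4
  - item_id: eat8
    prompt: Swallowing item 8
    levels:
      min: 0
      max: 4
  - item_id: eat9
    prompt: Swallowing item 9
    levels:
      min: 0
      max: 4
  - item_id: eat10
    prompt: Swallowing item 10
    levels:
      min: 0
      max: 4
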