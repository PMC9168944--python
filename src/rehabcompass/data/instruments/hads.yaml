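instrument_id: hads
name: Hospital Anxiety and Depression Scale
scoring_rule: sum-rescale
higher_is_better: false
domains:
- domain_id: anxiety
  name: Anxiety
  raw_min: 0
  raw_max: 21
  items:
  - item_id: hads_a1
    prompt: Anxiety item 1
    levels:
      min: 0
      max: 3
  - item_id: hads_a2
    prompt: Anxiety item 2
    levels:
      min: 0
      max: 3
  - item_id: hads_a3
    prompt: Anxiety item 3
    levels:
      min: 0
      max: 3
  - item_id: hads_a4
    prompt: Anxiety item 4
    levels:
      min: 0
      max: 3
  - item_id: hads_a5
    prompt: Anxiety item 5
    levels:
      min: 0
      max: 3
  - item_id: hads_a6
    prompt: Anxiety item 6
    levels:
      min: 0
      max: 3
  - item_id: hads_a7
    prompt: Anxiety item 7
    levels:
      min: 0
      max: 3
- domain_id: depression
  name: Depression
  raw_min: 0
  raw_max: 21
  items:
  - item_id: hads_d1
    prompt: Depression item 1
    levels:
      min: 0
      max: 3
  - item_id: hads_d2
    prompt: Depression item 2
    levels:
      min: 0
      max: 3
  - item_id: hads_d3
    prompt: Depression item 3
    levels:
      min: 0
      max: 3
  - item_id: hads_d4
    prompt: Depression item 4
    levels:
      min: 0
      max: 3
  - item_id: hads_d5
    prompt: Depression item 5
    levels:
      min: 0
      max: 3
  - item_id: hads_d6
    prompt: Depression item 6
    levels:
      min: 0
      max: 3
  - item_id: hads_d7
    prompt: Depression item 7
    levels:
      min: 0
      max: 3
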