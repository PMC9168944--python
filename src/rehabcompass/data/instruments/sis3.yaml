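instrument_id: sis3
name: Stroke Impact Scale 3.0
scoring_rule: mean-rescale
higher_is_better: true
domains:
- domain_id: strength
  name: Strength
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sis1_1
    prompt: Strength item 1
    levels:
      min: 1
      max: 5
  - item_id: sis1_2
    prompt: Strength item 2
    levels:
      min: 1
      max: 5
  - item_id: sis1_3
    prompt: Strength item 3
    levels:
      min: 1
      max: 5
  - item_id: sis1_4
    prompt: Strength item 4
    levels:
      min: 1
      max: 5
- domain_id: memory
  name: Memory and thinking
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sis2_1
    prompt: Memory and thinking item 1
    levels:
      min: 1
      max: 5
  - item_id: sis2_2
    prompt: Memory and thinking item 2
    levels:
      min: 1
      max: 5
  - item_id: sis2_3
    prompt: Memory and thinking item 3
    levels:
      min: 1
      max: 5
  - item_id: sis2_4
    prompt: Memory and thinking item 4
    levels:
      min: 1
      max: 5
  - item_id: sis2_5
    prompt: Memory and thinking item 5
    levels:
      min: 1
      max: 5
  - item_id: sis2_6
    prompt: Memory and thinking item 6
    levels:
      min: 1
      max: 5
  - item_id: sis2_7
    prompt: Memory and thinking item 7
    levels:
      min: 1
      max: 5
- domain_id: emotion
  name: Emotion
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sis3_1
    prompt: Emotion item 1
    levels:
      min: 1
      max: 5
  - item_id: sis3_2
    prompt: Emotion item 2
    levels:
      min: 1
      max: 5
  - item_id: sis3_3
    prompt: Emotion item 3
    levels:
      min: 1
      max: 5
  - item_id: sis3_4
    prompt: Emotion item 4
    levels:
      min: 1
      max: 5
  - item_id: sis3_5
    prompt: Emotion item 5
    levels:
      min: 1
      max: 5
  - item_id: sis3_6
    prompt: Emotion item 6
    levels:
      min: 1
      max: 5
  - item_id: sis3_7
    prompt: Emotion item 7
    levels:
      min: 1
      max: 5
  - item_id: sis3_8
    prompt: Emotion item 8
    levels:
      min: 1
      max: 5
  - item_id: sis3_9
    prompt: Emotion item 9
    levels:
      min: 1
      max: 5
- domain_id: communication
  name: Communication
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sis4_1
    prompt: Communication item 1
    levels:
      min: 1
      max: 5
  - item_id: sis4_2
    prompt: Communication item 2
    levels:
      min: 1
      max: 5
  - item_id: sis4_3
    prompt: Communication item 3
    levels:
      min: 1
      max: 5
  - item_id: sis4_4
    prompt: Communication item 4
    levels:
      min: 1
      max: 5
  - item_id: sis4_5
    prompt: Communication item 5
    levels:
      min: 1
      max: 5
  - item_id: sis4_6
    prompt: Communication item 6
    levels:
      min: 1
      max: 5
  - item_id: sis4_7
    prompt: Communication item 7
    levels:
      min: 1
      max: 5
- domain_id: adl
  name: Activities of daily living
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sis5_1
    prompt: Activities of daily living item 1
    levels:
      min: 1
      max: 5
  - item_id: sis5_2
    prompt: Activities of daily living item 2
    levels:
      min: 1
      max: 5
  - item_id: sis5_3
    prompt: Activities of daily living item 3
    levels:
      min: 1
      max: 5
  - item_id: sis5_4
    prompt: Activities of daily living item 4
    levels:
      min: 1
      max: 5
  - item_id: sis5_5
    prompt: Activities of daily living item 5
    levels:
      min: 1
      max: 5
  - item_id: sis5_6
    prompt: Activities of daily living item 6
    levels:
      min: 1
      max: 5
  - item_id: sis5_7
    prompt: Activities of daily living item 7
    levels:
      min: 1
      max: 5
  - item_id: sis5_8
    prompt: Activities of daily living item 8
    levels:
      min: 1
      max: 5
  - item_id: sis5_9
    prompt: Activities of daily living item 9
    levels:
      min: 1
      max: 5
  - item_id: sis5_10
    prompt: Activities of daily living item 10
    levels:
      min: 1
      max: 5
- domain_id: mobility
  name: Mobility
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sis6_1
    prompt: Mobility item 1
    levels:
      min: 1
      max: 5
  - item_id: sis6_2
    prompt: Mobility item 2
    levels:
      min: 1
      max: 5
  - item_id: sis6_3
    prompt: Mobility item 3
    levels:
      min: 1
      max: 5
  - item_id: sis6_4
    prompt: Mobility item 4
    levels:
      min: 1
      max: 5
  - item_id: sis6_5
    prompt: Mobility item 5
    levels:
      min: 1
      max: 5
  - item_id: sis6_6
    prompt: Mobility item 6
    levels:
      min: 1
      max: 5
  - item_id: sis6_7
    prompt: Mobility item 7
    levels:
      min: 1
      max: 5
  - item_id: sis6_8
    prompt: Mobility item 8
    levels:
      min: 1
      max: 5
  - item_id: sis6_9
    prompt: Mobility item 9
    levels:
      min: 1
      max: 5
- domain_id: hand
  name: Hand function
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sis7_1
    prompt: Hand function item 1
    levels:
      min: 1
      max: 5
  - item_id: sis7_2
    prompt: Hand function item 2
    levels:
      min: 1
      max: 5
  - item_id: sis7_3
    prompt: Hand function item 3
    levels:
      min: 1
      max: 5
  - item_id: sis7_4
    prompt: Hand function item 4
    levels:
      min: 1
      max: 5
  - item_id: sis7_5
    prompt: Hand function item 5
    levels:
      min: 1
      max: 5
- domain_id: participation
  name: Participation
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sis8_1
    prompt: Participation item 1
    levels:
      min: 1
      max: 5
  - item_id: sis8_2
    prompt: Participation item 2
    levels:
      min: 1
      max: 5
  - item_id: sis8_3
    prompt: Participation item 3
    levels:
      min: 1
      max: 5
  - item_id: sis8_4
    prompt: Participation item 4
    levels:
      min: 1
      max: 5
  - item_id: sis8_5
    prompt: Participation item 5
    levels:
      min: 1
      max: 5
  - item_id: sis8_6
    prompt: Participation item 6
    levels:
      min: 1
      max: 5
  - item_id: sis8_7
    prompt: Participation item 7
    levels:
      min: 1
      max: 5
  - item_id: sis8_8
    prompt: Participation item 8
    levels:
      min: 1
      max: 5
- domain_id: recovery
  name: Stroke recovery
  scoring_rule: passthrough-0-100
  raw_min: 0
  raw_max: 100
  items:
  - item_id: sis9_1
    prompt: Stroke recovery rating
    levels:
      min: 0
      max: 100
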