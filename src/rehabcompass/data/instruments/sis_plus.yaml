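instrument_id: sis_plus
name: SIS additional questions
scoring_rule: mean-rescale
higher_is_better: true
domains:
- domain_id: sensory
  name: Sensory disturbances
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sp_sens1
    prompt: Sensory item 1
    levels:
      min: 1
      max: 5
  - item_id: sp_sens2
    prompt: Sensory item 2
    levels:
      min: 1
      max: 5
- domain_id: sleep
  name: Sleep disturbances
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sp_sleep1
    prompt: Sleep item 1
    levels:
      min: 1
      max: 5
  - item_id: sp_sleep2
    prompt: Sleep item 2
    levels:
      min: 1
      max: 5
- domain_id: pain
  name: Pain
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sp_pain1
    prompt: Pain item 1
    levels:
      min: 1
      max: 5
- domain_id: continence
  name: Continence
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sp_cont1
    prompt: Continence item 1
    levels:
      min: 1
      max: 5
  - item_id: sp_cont2
    prompt: Continence item 2
    levels:
      min: 1
      max: 5
- domain_id: sexuality
  name: Sexual function
  raw_min: 1
  raw_max: 5
  items:
  - item_id: sp_sex1
    prompt: Sexuality item 1
    levels:
      min: 1
      max: 5
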