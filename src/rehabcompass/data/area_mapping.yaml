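# Default domain -> area mapping for the seven-area compass.
# Memberships are a documented reconstruction and may be overridden per
# deployment; area order defines the clockwise sector order from 12 o'clock.
areas:
  - area_id: life
    name: Life
    members:
      - [sis3, adl]
      - [sis3, participation]
      - [smrsq, disability]
      - [eq5d3l, health_rating]
      - [sis3, recovery]
  - area_id: cognition
    name: Cognition
    members:
      - [sis3, memory]
      - [sis3, communication]
  - area_id: emotion
    name: Emotion
    members:
      - [sis3, emotion]
      - [hads, anxiety]
      - [hads, depression]
  - area_id: fatigue
    name: Fatigue
    members:
      - [fas, fatigue]
      - [sis_plus, sleep]
  - area_id: sexuality_continence
    name: Sexuality and continence
    members:
      - [sis_plus, sexuality]
      - [sis_plus, continence]
  - area_id: sensory
    name: Sensory function
    members:
      - [sis_plus, sensory]
      - [sis_plus, pain]
  - area_id: motor
    name: Motor function
    members:
      - [sis3, strength]
      - [sis3, hand]
      - [sis3, mobility]
      - [eat10, swallowing]
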