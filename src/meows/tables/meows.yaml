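name: MEOWS
rules:
- parameter: resp_rate
  bands:
  - points: 2
    from: 21.0
    to: 25.0
  - points: 3
    below: 12.0
  - points: 3
    above: 25.0
- parameter: spo2
  bands:
  - points: 2
    from: 92.0
    to: 95.0
  - points: 3
    below: 92.0
- parameter: o2_supplement
  bands:
  - points: 2
    when: true
- parameter: temperature
  bands:
  - points: 2
    from: 37.3
    to: 37.7
  - points: 3
    above: 37.7
  - points: 3
    below: 36.0
- parameter: sbp
  bands:
  - points: 1
    from: 140.0
    to: 150.0
  - points: 2
    from: 150.0
    to: 160.0
  - points: 3
    above: 160.0
  - points: 3
    below: 90.0
- parameter: dbp
  bands:
  - points: 1
    from: 90.0
    to: 100.0
  - points: 2
    from: 100.0
    to: 110.0
  - points: 3
    above: 110.0
- parameter: heart_rate
  bands:
  - points: 1
    from: 110.0
    to: 120.0
  - points: 2
    from: 120.0
    to: 130.0
  - points: 2
    from: 50.0
    to: 60.0
  - points: 3
    above: 130.0
  - points: 3
    below: 50.0
- parameter: avpu
  bands:
  - points: 3
    any_of:
    - P
    - U
    - V
- parameter: vas_pain
  bands:
  - points: 2
    from: 4.0
    to: 7.0
  - points: 3
    at_least: 7.0
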