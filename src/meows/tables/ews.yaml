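name: EWS
rules:
- parameter: heart_rate
  bands:
  - points: 1
    from: 41.0
    to: 50.0
  - points: 1
    from: 101.0
    to: 110.0
  - points: 2
    from: 111.0
    to: 129.0
  - points: 2
    below: 40.0
  - points: 3
    above: 130.0
- parameter: sbp
  bands:
  - points: 1
    from: 81.0
    to: 100.0
  - points: 2
    from: 71.0
    to: 80.0
  - points: 2
    above: 200.0
  - points: 3
    below: 70.0
- parameter: resp_rate
  bands:
  - points: 1
    from: 15.0
    to: 20.0
  - points: 2
    from: 21.0
    to: 29.0
  - points: 2
    below: 8.0
  - points: 3
    above: 30.0
- parameter: temperature
  bands:
  - points: 1
    from: 35.1
    to: 36.5
  - points: 1
    above: 37.5
  - points: 2
    below: 35.0
- parameter: avpu
  bands:
  - points: 1
    any_of:
    - V
  - points: 2
    any_of:
    - P
  - points: 3
    any_of:
    - U
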