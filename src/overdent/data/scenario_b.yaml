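horizon: 10
failure_rates:
  implant_six:
    low: 0.014
    mode: 0.018
    high: 0.023
  implant_four:
    low: 0.03
    mode: 0.037
    high: 0.046
  denture_six:
    low: 0.015
    mode: 0.026
    high: 0.044
  denture_four:
    low: 0.022
    mode: 0.035
    high: 0.069
  denture_no_implants:
    low: 0.01
    mode: 0.05
    high: 0.1
satisfaction:
  scores:
    6: 0.89
    5: 0.88
    4: 0.85
    3: 0.82
    2: 0.77
    1: 0.7
    0: 0.63
  repair_adjustment:
    low: 0.8
    mode: 0.9
    high: 0.99
costs:
  factors:
  - 1.0
  - 2.3
  - 3.5
  labor:
    six_new:
    - 1472.67
    - 2990.86
    - 4392.27
    four_new:
    - 1130.07
    - 2199.98
    - 3190.67
    repair_implant:
    - 206.68
    - 267.35
    - 323.39
    repair_denture:
    - 65.19
    - 84.93
    - 103.16
  material:
    six_new: 5070.3
    four_new: 4507.82
    repair_implant: 160.0
    repair_denture: 50.0
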