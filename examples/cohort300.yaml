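n_pregnancies: 300
seed: 7
paracetamol_window_rate: 0.55
persistence: 0.0
clusters:
- name: high intensity use
  weight: 0.0019431376559623645
  rates:
    N02BE01: 0.83
    N02AA05: 0.95
    M01AE01: 0.95
    A02BC01: 0.22
    R06AE07: 0.16
  covariate_shifts:
    education:
    - 0.79
    - 0.21
    alcohol_use:
    - 0.21
    - 0.79
    pain:
    - 0.84
    - 0.16
    infections:
    - 0.95
    - 0.05
    mental_illness:
    - 0.32
    - 0.68
    asthma:
    - 0.32
    - 0.68
- name: low intensity use
  weight: 0.5011249744323992
  rates:
    N02BE01: 0.69
    M01AE01: 0.015
    J01CA04: 0.015
    R06AE07: 0.01
    A02BC01: 0.01
    H03AA01: 0.01
  covariate_shifts:
    parity:
    - 0.375
    - 0.625
    infections:
    - 0.6
    - 0.4
    mental_illness:
    - 0.025
    - 0.975
    asthma:
    - 0.042
    - 0.958
- name: moderate intensity use
  weight: 0.27030067498465943
  rates:
    N02BE01: 0.105
    J01CA04: 0.95
    J01XE01: 0.02
    R06AE07: 0.01
  covariate_shifts:
    infections:
    - 0.81
    - 0.19
    mental_illness:
    - 0.06
    - 0.94
    asthma:
    - 0.13
    - 0.87
- name: moderate intensity use, more mental illness
  weight: 0.18521169973409696
  rates:
    N02BE01: 0.36
    N06AB04: 0.95
    N06AX16: 0.06
    M01AE01: 0.02
    J01CA04: 0.02
    R06AE07: 0.01
  covariate_shifts:
    infections:
    - 0.85
    - 0.15
    mental_illness:
    - 0.123
    - 0.877
    asthma:
    - 0.204
    - 0.796
- name: high intensity use, more asthma
  weight: 0.04141951319288198
  rates:
    N02BE01: 0.5
    R03AC02: 0.95
    R03BA02: 0.5
    J01CA04: 0.02
    M01AE01: 0.02
    R06AE07: 0.01
  covariate_shifts:
    bmi:
    - 0.015
    - 0.465
    - 0.52
    infections:
    - 0.89
    - 0.11
    mental_illness:
    - 0.175
    - 0.825
    asthma:
    - 0.358
    - 0.642
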