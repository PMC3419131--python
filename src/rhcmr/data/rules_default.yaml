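# Default screening rules for the detection of PH (mPAP >= 25 mmHg).
# direction GE_POSITIVE: value >= cutpoint is test-positive;
#           LE_POSITIVE: value <= cutpoint is test-positive.
# The PA relative area change rule is LE_POSITIVE (a stiff, hypertensive
# artery pulses less), at 15%.
rules:
  - {metric: rvedvi,                cutpoint: 75.0, direction: GE_POSITIVE}
  - {metric: rv_mass_index,         cutpoint: 20.0, direction: GE_POSITIVE}
  - {metric: vmi,                   cutpoint: 0.4,  direction: GE_POSITIVE}
  - {metric: rvef,                  cutpoint: 35.0, direction: LE_POSITIVE}
  - {metric: rvsvi,                 cutpoint: 30.0, direction: LE_POSITIVE}
  - {metric: tapse,                 cutpoint: 2.0,  direction: LE_POSITIVE}
  - {metric: f_taad,                cutpoint: 25.0, direction: LE_POSITIVE}
  - {metric: sfd,                   cutpoint: 1.0,  direction: LE_POSITIVE}
  - {metric: f_sfd,                 cutpoint: 25.0, direction: LE_POSITIVE}
  - {metric: rvrac,                 cutpoint: 30.0, direction: LE_POSITIVE}
  - {metric: sei,                   cutpoint: 1.2,  direction: GE_POSITIVE}
  - {metric: dei,                   cutpoint: 1.17, direction: GE_POSITIVE}
  - {metric: pa_average_velocity,   cutpoint: 10.0, direction: LE_POSITIVE}
  - {metric: pa_retrograde_flow,    cutpoint: 0.3,  direction: GE_POSITIVE}
  - {metric: pa_rac,                cutpoint: 15.0, direction: LE_POSITIVE}
  - {metric: pa_systolic_area,      cutpoint: 8.0,  direction: GE_POSITIVE}
  - {metric: pa_diastolic_area,     cutpoint: 6.0,  direction: GE_POSITIVE}
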