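# Calibration reproducing the published per-limb arithmetic.
# Replacement counting: count_minus_one (initial fitting funded outside the
# 40-year stream).  The single 40-year care constant of GBP 710,000
# (17,750/year) is over-determined: it must explain both the transtibial
# (0.87M) and transfemoral (1.16M) base packages given the replacement
# streams, and does.
name: printed
catalogue:
  transtibial: 9946
  through_knee: 27154
  transfemoral: 27154
  foot: 9747
care:
  annual_healthy: 17750
  annual_chronic: 17750
replacement:
  period: 2.3
  convention: count_minus_one
  mortality_weighted: false
markov:
  horizon: 40
  discount_rate: 0.0
  initial_occupancy: [1.0, 0.0, 0.0]
transitions:
  healthy: [0.960, 0.035, 0.005]
  chronic: [0.000, 0.930, 0.070]
  dead:    [0.000, 0.000, 1.000]
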