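# Canonical scenario behind the cohort headline total and the cycle-length
# sensitivity.  Replacement counting: continuous (horizon / period), the
# convention under which the prosthetic stream scales exactly as
# baseline_period / new_period.  The 40-year care constant of GBP 692,400
# (17,310/year) likewise reproduces both published base packages (0.87M
# transtibial, 1.16M transfemoral) under this convention, and gives the
# representative single transtibial patient a prosthetic cost share of
# 0.1999, the share implied by the published one-way sensitivity results.
# Calibrated once against the published figures, then frozen.
name: canonical
catalogue:
  transtibial: 9946
  through_knee: 27154
  transfemoral: 27154
  foot: 9747
care:
  annual_healthy: 17310
  annual_chronic: 17310
replacement:
  period: 2.3
  convention: continuous
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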