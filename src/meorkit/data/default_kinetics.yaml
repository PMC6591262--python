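# Default two-step denitrification calibration (fitted-by-us).
# Chosen so that, from a small inoculum with 10 mM nitrate and an
# ethylbenzene-equivalent donor supply, nitrate is fully converted to
# nitrite within 2-4 days, the transient nitrite peak exceeds 5 mM and
# clears below 0.5 mM by day 9, and a chemostat on a 10 mM nitrate /
# 1.2 mM donor feed settles near OD600 3.1-3.35.
# These are model-calibration values, not measured rate constants.
kinetics:
  qmax1: 8.0     # mM nitrate per OD600 per day
  qmax2: 4.0     # mM nitrite per OD600 per day
  K1: 0.2        # mM nitrate
  K2: 0.5        # mM nitrite
  Y: 2.65        # OD600 per mM donor oxidized
  X0: 0.05       # OD600 inoculum
  donor0: 1.24   # mM donor, aqueous-equivalent
  K_donor: 0.01  # mM donor
  gamma_donor: 42.0  # electrons per mol donor (ethylbenzene)
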