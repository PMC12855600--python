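# SYNTHETIC relapse-time fixture (NOT patient data).
# 28 records: 4 relapse diagnoses within 24 months of withdrawal and 24
# records administratively censored at 24 months, matching the published
# summary (4/28 events by 2 years).  The four event times (whole months,
# clustered early) were chosen so that the five parametric fits reproduce
# the published qualitative structure of the extrapolation figure and the
# reported base-case incrementals: the exponential fit attains the best
# (lowest) BIC with small differences across families; the Gompertz fit
# has a negative shape and plateaus (the favourable scenario); the
# lognormal fit has a decreasing long-term hazard and lies between the
# Gompertz plateau and the steeply falling families.
time,event
3.0,1
7.0,1
12.0,1
19.0,1
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
24.0,0
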