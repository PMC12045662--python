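# Default functional-heart-age model parameters (version 1).
# Three LA ESV segments with boundary volumes belonging to the mid segment,
# plus half-open LA EF correction bands; EF >= 62 % adds nothing.
esv_breakpoints_ml: [15.0, 50.0]
segments:
- intercept_yr: 6.4026
  slope_yr_per_ml: 0.2468
- intercept_yr: -18.0342
  slope_yr_per_ml: 2.3140
- intercept_yr: 87.9207
  slope_yr_per_ml: 0.05241
ef_bands:
- ef_upper_pct: 55.0
  correction_yr: 20.0
- ef_upper_pct: 58.0
  correction_yr: 15.0
- ef_upper_pct: 60.0
  correction_yr: 5.0
- ef_upper_pct: 62.0
  correction_yr: 2.0
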