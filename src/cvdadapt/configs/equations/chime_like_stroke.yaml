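# Stylised CHIME-like Weibull risk equation for stroke.
# Coefficients are plausible per-unit log hazard ratios for a T2D cohort,
# not transcriptions of any published vector; the intercept is calibrated
# so the mean 5-year risk over the default covariate distribution is 6.80%.
name: chime_stroke
outcome: stroke
form: weibull_cumhaz
coefficients:
  age: 0.08
  male: 0.30
  hba1c: 0.25
  sbp: 0.012
  egfr: -0.008
  smoking_current: 0.50
  prior_stroke: 0.80
centering:
  age: 64.0
  hba1c: 7.8
  sbp: 133.0
  egfr: 80.0
intercept: -5.136997
shape: 1.1
horizon: 5.0
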