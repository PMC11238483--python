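# Three-stratum multiplier for the CHIME-like MI equation, site B (NTUH-style).
# Printed bounds 2.5% and 10%; strata are half-open [lower, upper), so the
# interior bounds 2.5 and 10 belong to the stratum above them.
equation: chime_mi
institution: NTUH
unit: percent
strata:
  - {lower: 0, upper: 2.5, delta: -1.55474}
  - {lower: 2.5, upper: 10, delta: -1.29655}
  - {lower: 10, upper: 100, delta: -0.96124}
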