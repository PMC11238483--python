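# Three-stratum multiplier for the CHIME-like stroke equation, site B.
equation: chime_stroke
institution: NTUH
unit: percent
strata:
  - {lower: 0, upper: 8.5, delta: -1.37453272}
  - {lower: 8.5, upper: 17, delta: -1.00104983}
  - {lower: 17, upper: 100, delta: -0.25721347}
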