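# Three-stratum multiplier for the CHIME-like stroke equation, site A.
equation: chime_stroke
institution: NCKUH
unit: percent
strata:
  - {lower: 0, upper: 8, delta: -0.540353318}
  - {lower: 8, upper: 11, delta: -0.726038047}
  - {lower: 11, upper: 100, delta: -0.46372315}
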