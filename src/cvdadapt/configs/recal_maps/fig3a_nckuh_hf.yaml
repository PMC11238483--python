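# Global institutional multiplier for the CHIME-like HF equation, site A.
equation: chime_hf
institution: NCKUH
unit: percent
strata:
  - {lower: 0, upper: 100, delta: -0.201793786}
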