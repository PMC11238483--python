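# Global institutional multiplier for the CHIME-like HF equation, site B.
equation: chime_hf
institution: NTUH
unit: percent
strata:
  - {lower: 0, upper: 100, delta: -1.022724239}
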