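# Global institutional multiplier for the CHIME-like MI equation, site A
# (NCKUH-style): Risk_recal = exp[ln(Risk) - 0.7961947].
equation: chime_mi
institution: NCKUH
unit: percent
strata:
  - {lower: 0, upper: 100, delta: -0.7961947}
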