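# Illustrative diagnosis / medication code lists for cohort selection,
# history flags, and outcome ascertainment.  Codes match by prefix after
# removing dots.  This is a deliberately small teaching vocabulary, not a
# complete clinical code set.
t2d:
  ICD9: ["250"]
  ICD10: ["E11"]
outcomes:
  mi:
    ICD9: ["410"]
    ICD10: ["I21", "I22"]
  stroke:
    ICD9: ["433", "434", "436"]
    ICD10: ["I63", "I64"]
  hf:
    ICD9: ["428"]
    ICD10: ["I50"]
histories:
  prior_mi:
    ICD9: ["410", "412"]
    ICD10: ["I21", "I22", "I252"]
  prior_stroke:
    ICD9: ["433", "434", "436"]
    ICD10: ["I63", "I64", "I69"]
  prior_hf:
    ICD9: ["428"]
    ICD10: ["I50"]
  ihd:
    ICD9: ["411", "413", "414"]
    ICD10: ["I20", "I24", "I25"]
  af:
    ICD9: ["42731"]
    ICD10: ["I48"]
  ckd:
    ICD9: ["585"]
    ICD10: ["N18"]
medications:
  insulin: ["A10A"]
  glucose_lowering: ["A10B"]
  antihypertensive: ["C02", "C03", "C07", "C08", "C09"]
  lipid_lowering: ["C10"]
  antiplatelet: ["B01AC"]
# any of these record types counts as activity for the continuous
# follow-up requirement
activity_tables: [diagnosis, prescription, lab_result, vital_sign, smoking]
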