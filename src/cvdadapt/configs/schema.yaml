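# Controlled vocabularies for the six-dimension CDM.
# test_name values are the controlled laboratory vocabulary; units are
# informative only (values are assumed already harmonised to these units).
vocabularies:
  sex: [female, male]
  code_system: [ICD9, ICD10]
  setting: [outpatient, inpatient, emergency]
  test_name: [hba1c, ldl, hdl, egfr, hemoglobin, wbc]
  measure: [sbp, dbp, height, weight, bmi]
  smoking_status: [never, former, current]
units:
  hba1c: "%"
  ldl: mg/dL
  hdl: mg/dL
  egfr: mL/min/1.73m2
  hemoglobin: g/dL
  wbc: 10^9/L
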