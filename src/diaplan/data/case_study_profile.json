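{
  "patient_id": "patient_1",
  "profile_id": "profile_1",
  "date": "2017-01-15",
  "demographics": {
    "age": 50,
    "sex": "male",
    "height_cm": 180,
    "weight_kg": 100,
    "social_state": "poor",
    "activity_level": "light",
    "language": "english",
    "education_level": "university"
  },
  "labs": [
    {"test": "hba1c", "value": 8.1, "unit": "%", "date": "2017-01-10"},
    {"test": "fasting_plasma_glucose", "value": 190, "unit": "mg/dL", "date": "2017-01-10"}
  ],
  "records": [
    {"kind": "disease", "code": "lactic_acidosis"},
    {"kind": "disease", "code": "nonparalytic_stroke"},
    {"kind": "medication", "code": "dofetilide"}
  ],
  "has_previous_treatment_plan": false
}
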