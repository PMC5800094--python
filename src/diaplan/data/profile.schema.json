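{
  "$comment": "Descriptive schema for patient profile documents. Validation is performed by diaplan.profile_model.load_profile; this file documents the contract.",
  "type": "object",
  "required": ["patient_id", "date", "demographics", "labs", "records", "has_previous_treatment_plan"],
  "properties": {
    "patient_id": {"type": "string"},
    "profile_id": {"type": "string"},
    "date": {"type": "string", "format": "date"},
    "demographics": {
      "type": "object",
      "required": ["age", "sex", "height_cm", "weight_kg", "social_state", "activity_level"],
      "properties": {
        "age": {"type": "integer", "minimum": 0, "maximum": 130},
        "sex": {"enum": ["male", "female"]},
        "height_cm": {"type": "number", "exclusiveMinimum": 0, "maximum": 272},
        "weight_kg": {"type": "number", "exclusiveMinimum": 0, "maximum": 650},
        "social_state": {"enum": ["poor", "intermediate", "rich"]},
        "activity_level": {"enum": ["sedentary", "light", "moderate", "very_active", "extra_active"]},
        "language": {"type": "string"},
        "education_level": {"type": "string"}
      }
    },
    "labs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["test", "value", "unit", "date"],
        "properties": {
          "test": {"type": "string"},
          "value": {"type": "number"},
          "unit": {"enum": ["%", "mg/dL"]},
          "date": {"type": "string", "format": "date"}
        }
      }
    },
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kind", "code"],
        "properties": {
          "kind": {"enum": ["symptom", "disease", "medication"]},
          "code": {"type": "string"},
          "severity": {"type": ["string", "null"]},
          "duration_days": {"type": ["integer", "null"]}
        }
      }
    },
    "has_previous_treatment_plan": {"type": "boolean"}
  }
}
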