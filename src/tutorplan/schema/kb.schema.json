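{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://tutorplan.example.org/schema/kb.schema.json",
  "title": "tutorplan knowledge base",
  "description": "Native JSON/YAML dialect of the eLearning knowledge base. The loader enforces this structure itself (with JSON-pointer error locations); this document is the normative description of the format.",
  "type": "object",
  "required": ["concepts", "facts", "profiles", "buks", "patients"],
  "properties": {
    "concepts": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["code", "category"],
        "properties": {
          "code": {
            "type": "object",
            "required": ["code", "preferred_name"],
            "properties": {
              "system": {"type": "string"},
              "code": {"type": "string", "minLength": 1},
              "preferred_name": {"type": "string", "minLength": 1}
            }
          },
          "category": {"enum": ["condition", "observation", "treatment_option"]},
          "treatment_subtype": {"enum": ["medication", "service", "nutrition_order", "care_plan"]},
          "parent_id": {"type": "string"},
          "may_treat": {"type": "array", "items": {"type": "string"}},
          "may_prevent": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "facts": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["text", "about_condition"],
        "properties": {
          "text": {"type": "string", "minLength": 1},
          "about_condition": {"type": "string"}
        }
      }
    },
    "profiles": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "condition_facts": {"type": "array", "items": {"type": "string"}},
          "findings": {"type": "array", "items": {"type": "string"}},
          "complications": {"type": "array", "items": {"type": "string"}},
          "risk_factors": {"type": "array", "items": {"type": "string"}},
          "treatment_options": {"type": "array", "items": {"type": "string"}},
          "prevention_options": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "buks": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["kind", "refers_to", "theme", "bloom", "comprehension", "explanation"],
        "properties": {
          "kind": {"enum": ["content", "qa"]},
          "refers_to": {"type": "string"},
          "theme": {"enum": ["dosage", "monitoring_tests", "direct_effects", "side_effects", "risky_events", "diet_restrictions", "general"]},
          "bloom": {"enum": ["lower", "higher"]},
          "comprehension": {"enum": ["low", "medium", "high"]},
          "explanation": {"$ref": "#/$defs/renderings"},
          "question": {"$ref": "#/$defs/renderings"},
          "choices": {"type": "array", "items": {"type": "string"}, "minItems": 2},
          "correct_choice_index": {"type": "integer", "minimum": 0},
          "sequence_index": {"type": "integer", "minimum": 0}
        }
      }
    },
    "patients": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["comprehension", "preferred_styles", "condition_id", "treatment_request"],
        "properties": {
          "comprehension": {"enum": ["low", "medium", "high"]},
          "preferred_styles": {"type": "array", "items": {"enum": ["V", "A", "R", "K"]}, "minItems": 1, "uniqueItems": true},
          "condition_id": {"type": "string"},
          "treatment_request": {
            "type": "object",
            "required": ["treatment_option_id"],
            "properties": {
              "treatment_option_id": {"type": "string"},
              "dose": {"type": "string"},
              "timing": {"type": "string"},
              "rate": {"type": "string"}
            }
          },
          "demographics": {"type": "object"},
          "performance_log": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["buk_id", "correct", "tick"],
              "properties": {
                "buk_id": {"type": "string"},
                "correct": {"type": "boolean"},
                "tick": {"type": "integer"}
              }
            }
          }
        }
      }
    }
  },
  "$defs": {
    "renderings": {
      "type": "object",
      "description": "Map from VARK style letter to one rendering; question renderings may only use styles A and R.",
      "propertyNames": {"enum": ["V", "A", "R", "K"]},
      "additionalProperties": {
        "type": "object",
        "properties": {
          "text": {"type": "string"},
          "asset_ref": {"type": "string"}
        }
      }
    }
  }
}
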