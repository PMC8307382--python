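{
  "buks": {
    "bp_content_exercises": {
      "bloom": "lower",
      "comprehension": "low",
      "explanation": {
        "R": {
          "text": "Avoid exercises that jolt or twist the lower back while it hurts: sit-ups with straight legs, toe touches, and heavy lifting above the waist are not recommended for people with back problems."
        },
        "V": {
          "asset_ref": "img/avoid_exercises.png",
          "text": "Poster of exercises to avoid with back problems."
        }
      },
      "kind": "content",
      "refers_to": "back_exercise",
      "theme": "risky_events"
    },
    "bp_qa_1": {
      "bloom": "lower",
      "choices": [
        "Low-grade pain that is there most of the time and sometimes flares up",
        "Sharp pain only when sneezing",
        "Pain only at night"
      ],
      "comprehension": "low",
      "correct_choice_index": 0,
      "explanation": {
        "K": {
          "asset_ref": "exercise/seated_pelvic_tilt",
          "text": "Gently arch and flatten your lower back while seated: the dull ache you may feel at the end of the range is the kind of continuous, low-grade pain a worn disc causes."
        },
        "R": {
          "text": "A degenerated disc typically causes continuous, low-grade pain that occasionally flares into more severe pain."
        }
      },
      "kind": "qa",
      "question": {
        "A": {
          "asset_ref": "audio/bp_qa_1.ogg",
          "text": "Which kind of pain is most typical of a worn lumbar disc?"
        },
        "R": {
          "text": "Which kind of pain is most typical of a worn lumbar disc?"
        }
      },
      "refers_to": "back_pain",
      "sequence_index": 1,
      "theme": "general"
    },
    "bp_qa_2": {
      "bloom": "higher",
      "choices": [
        "Stay in bed until the pain is completely gone",
        "Keep gently active and return to normal movement as the flare settles",
        "Stop all exercise for a month"
      ],
      "comprehension": "medium",
      "correct_choice_index": 1,
      "explanation": {
        "R": {
          "text": "Flares of disc-related pain settle fastest with gentle activity; prolonged bed rest weakens the muscles that protect the spine."
        },
        "V": {
          "asset_ref": "img/flare_plan.png",
          "text": "Illustrated flare-up plan: gentle movement, gradual return to activity."
        }
      },
      "kind": "qa",
      "question": {
        "A": {
          "asset_ref": "audio/bp_qa_2.ogg",
          "text": "Which response to a flare after a long car ride applies what you have learned?"
        },
        "R": {
          "text": "Your back pain flares after a long car ride. Which response applies what you have learned?"
        }
      },
      "refers_to": "back_pain",
      "sequence_index": 1,
      "theme": "general"
    },
    "spine_qa_1": {
      "bloom": "lower",
      "choices": [
        "Cushioning discs",
        "Small muscles only"
      ],
      "comprehension": "low",
      "correct_choice_index": 0,
      "explanation": {
        "R": {
          "text": "Soft discs cushion the vertebrae."
        }
      },
      "kind": "qa",
      "question": {
        "R": {
          "text": "What sits between the bones of your spine?"
        }
      },
      "refers_to": "spine_anatomy",
      "theme": "general"
    }
  },
  "concepts": {
    "back_exercise": {
      "category": "treatment_option",
      "code": {
        "code": "229065009",
        "preferred_name": "back strengthening exercise programme",
        "system": "SNOMED-CT"
      },
      "may_prevent": [
        "ldd"
      ],
      "may_treat": [
        "ldd"
      ],
      "treatment_subtype": "care_plan"
    },
    "back_pain": {
      "category": "observation",
      "code": {
        "code": "279039007",
        "preferred_name": "Low back pain",
        "system": "SNOMED-CT"
      }
    },
    "ibuprofen": {
      "category": "treatment_option",
      "code": {
        "code": "387207008",
        "preferred_name": "ibuprofen",
        "system": "SNOMED-CT"
      },
      "may_treat": [
        "ldd"
      ],
      "parent_id": "nsaid",
      "treatment_subtype": "medication"
    },
    "ldd": {
      "category": "condition",
      "code": {
        "code": "240221008",
        "preferred_name": "Lumbar degenerative disc condition",
        "system": "SNOMED-CT"
      }
    },
    "nsaid": {
      "category": "treatment_option",
      "code": {
        "code": "372665008",
        "preferred_name": "non-steroidal anti-inflammatory medication",
        "system": "SNOMED-CT"
      },
      "may_treat": [
        "ldd"
      ],
      "treatment_subtype": "medication"
    },
    "obesity": {
      "category": "condition",
      "code": {
        "code": "414916001",
        "preferred_name": "Obesity",
        "system": "SNOMED-CT"
      }
    },
    "sciatica": {
      "category": "condition",
      "code": {
        "code": "23056005",
        "preferred_name": "Sciatica",
        "system": "SNOMED-CT"
      }
    },
    "spine_anatomy": {
      "category": "observation",
      "code": {
        "code": "421060004",
        "preferred_name": "Structure of the spine",
        "system": "SNOMED-CT"
      }
    },
    "stiffness": {
      "category": "observation",
      "code": {
        "code": "161874005",
        "preferred_name": "Morning stiffness of the spine",
        "system": "SNOMED-CT"
      }
    }
  },
  "facts": {
    "ldd_fact_wear": {
      "about_condition": "ldd",
      "text": "The discs between the vertebrae lose water and cushioning with age, which can cause low-grade, continuous back pain."
    }
  },
  "patients": {
    "anne": {
      "comprehension": "low",
      "condition_id": "ldd",
      "demographics": {
        "given_name": "Anne"
      },
      "performance_log": [
        {
          "buk_id": "spine_qa_1",
          "correct": false,
          "tick": 1
        },
        {
          "buk_id": "spine_qa_1",
          "correct": true,
          "tick": 2
        },
        {
          "buk_id": "spine_qa_1",
          "correct": true,
          "tick": 3
        }
      ],
      "preferred_styles": [
        "K",
        "V"
      ],
      "treatment_request": {
        "dose": "400 mg",
        "timing": "1 tablet/day",
        "treatment_option_id": "ibuprofen"
      }
    }
  },
  "profiles": {
    "ldd": {
      "complications": [
        "sciatica"
      ],
      "condition_facts": [
        "ldd_fact_wear"
      ],
      "findings": [
        "back_pain"
      ],
      "prevention_options": [
        "back_exercise"
      ],
      "risk_factors": [
        "obesity"
      ],
      "treatment_options": [
        "ibuprofen",
        "back_exercise"
      ]
    }
  }
}
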