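{
  "buks": {
    "af_content_2": {
      "bloom": "higher",
      "comprehension": "high",
      "explanation": {
        "R": {
          "text": "Anticoagulation medication slows the clotting cascade that vitamin K supports. Sudden changes in vitamin K intake — leafy greens, liver, some vegetable oils — shift the medication's effect, so a consistent diet matters more than strict avoidance."
        }
      },
      "kind": "content",
      "refers_to": "anticoagulant",
      "theme": "diet_restrictions"
    },
    "af_qa_1": {
      "bloom": "higher",
      "choices": [
        "A large spinach and kale salad",
        "A bowl of plain rice",
        "A glass of apple juice"
      ],
      "comprehension": "high",
      "correct_choice_index": 0,
      "explanation": {
        "R": {
          "text": "Leafy greens are rich in vitamin K, which counteracts anticoagulation medication; keep your intake steady rather than avoiding them entirely."
        },
        "V": {
          "asset_ref": "img/vitamin_k_chart.png",
          "text": "Chart of vitamin K content across common foods."
        }
      },
      "kind": "qa",
      "question": {
        "A": {
          "asset_ref": "audio/af_qa_1.ogg",
          "text": "Which food deserves the most attention while you take {treatment}?"
        },
        "R": {
          "text": "You are taking {treatment}. Which food on your plate deserves the most attention tonight?"
        }
      },
      "refers_to": "anticoagulant",
      "sequence_index": 1,
      "theme": "diet_restrictions"
    },
    "af_qa_3": {
      "bloom": "higher",
      "choices": [
        "Eat as much as you like, vegetables are always safe",
        "Keep portions similar from week to week",
        "Stop the medication on days you eat kale"
      ],
      "comprehension": "high",
      "correct_choice_index": 1,
      "explanation": {
        "R": {
          "text": "A steady weekly amount of vitamin K keeps the anticoagulation effect stable; never pause the medication on your own."
        },
        "V": {
          "asset_ref": "img/weekly_planner.png",
          "text": "Weekly meal-planning graphic for stable vitamin K intake."
        }
      },
      "kind": "qa",
      "question": {
        "A": {
          "asset_ref": "audio/af_qa_3.ogg",
          "text": "What is the safest way to enjoy a bumper kale crop while on {treatment}?"
        },
        "R": {
          "text": "Your vegetable garden produced a bumper crop of kale. While on {treatment}, what is the safest way to enjoy it?"
        }
      },
      "refers_to": "anticoagulant",
      "sequence_index": 2,
      "theme": "diet_restrictions"
    },
    "af_qa_4": {
      "bloom": "higher",
      "choices": [
        "Take the missed dose as soon as you remember, on the same day",
        "Take a double dose tomorrow morning",
        "Skip doses for the rest of the week"
      ],
      "comprehension": "high",
      "correct_choice_index": 0,
      "explanation": {
        "R": {
          "text": "A missed dose of {treatment} can be taken the same day, but never double the next dose: doubling raises bleeding risk sharply."
        },
        "V": {
          "asset_ref": "img/missed_dose.png",
          "text": "Decision diagram for a missed anticoagulant dose."
        }
      },
      "kind": "qa",
      "question": {
        "A": {
          "asset_ref": "audio/af_qa_4.ogg",
          "text": "What should you do about a missed morning dose of {treatment}?"
        },
        "R": {
          "text": "You realize at dinner that you forgot this morning's dose of {treatment} ({dose}, {timing}). What should you do?"
        }
      },
      "refers_to": "warfarin",
      "theme": "dosage"
    },
    "clot_qa_1": {
      "bloom": "lower",
      "choices": [
        "Stops bleeding after an injury",
        "Lowers blood pressure"
      ],
      "comprehension": "high",
      "correct_choice_index": 0,
      "explanation": {
        "R": {
          "text": "Clotting seals injured vessels to stop bleeding."
        }
      },
      "kind": "qa",
      "question": {
        "R": {
          "text": "What does blood clotting normally do?"
        }
      },
      "refers_to": "blood_clotting",
      "theme": "general"
    }
  },
  "concepts": {
    "af": {
      "category": "condition",
      "code": {
        "code": "49436004",
        "preferred_name": "Atrial fibrillation",
        "system": "SNOMED-CT"
      }
    },
    "anticoagulant": {
      "category": "treatment_option",
      "code": {
        "code": "372862008",
        "preferred_name": "anticoagulation medication",
        "system": "SNOMED-CT"
      },
      "may_prevent": [
        "stroke"
      ],
      "treatment_subtype": "medication"
    },
    "blood_clotting": {
      "category": "observation",
      "code": {
        "code": "50960005",
        "preferred_name": "Blood clotting",
        "system": "SNOMED-CT"
      }
    },
    "fatigue": {
      "category": "observation",
      "code": {
        "code": "84229001",
        "preferred_name": "Fatigue",
        "system": "SNOMED-CT"
      }
    },
    "hypertension": {
      "category": "condition",
      "code": {
        "code": "38341003",
        "preferred_name": "Hypertension",
        "system": "SNOMED-CT"
      }
    },
    "palpitations": {
      "category": "observation",
      "code": {
        "code": "80313002",
        "preferred_name": "Palpitations",
        "system": "SNOMED-CT"
      }
    },
    "rate_control": {
      "category": "treatment_option",
      "code": {
        "code": "372913009",
        "preferred_name": "rate control medication",
        "system": "SNOMED-CT"
      },
      "may_treat": [
        "af"
      ],
      "treatment_subtype": "medication"
    },
    "stroke": {
      "category": "condition",
      "code": {
        "code": "230690007",
        "preferred_name": "Stroke",
        "system": "SNOMED-CT"
      }
    },
    "warfarin": {
      "category": "treatment_option",
      "code": {
        "code": "372756006",
        "preferred_name": "warfarin",
        "system": "SNOMED-CT"
      },
      "may_prevent": [
        "stroke"
      ],
      "parent_id": "anticoagulant",
      "treatment_subtype": "medication"
    }
  },
  "facts": {
    "af_fact_age": {
      "about_condition": "af",
      "text": "The chance of developing atrial fibrillation increases with age."
    },
    "af_fact_rhythm": {
      "about_condition": "af",
      "text": "Atrial fibrillation is an irregular and often very rapid heart rhythm."
    }
  },
  "patients": {
    "mario": {
      "comprehension": "high",
      "condition_id": "af",
      "demographics": {
        "given_name": "Mario"
      },
      "performance_log": [
        {
          "buk_id": "clot_qa_1",
          "correct": true,
          "tick": 1
        },
        {
          "buk_id": "clot_qa_1",
          "correct": true,
          "tick": 2
        },
        {
          "buk_id": "clot_qa_1",
          "correct": true,
          "tick": 3
        }
      ],
      "preferred_styles": [
        "V",
        "R"
      ],
      "treatment_request": {
        "dose": "5 mg",
        "timing": "1 tablet/day",
        "treatment_option_id": "warfarin"
      }
    }
  },
  "profiles": {
    "af": {
      "complications": [
        "stroke"
      ],
      "condition_facts": [
        "af_fact_rhythm"
      ],
      "findings": [
        "palpitations",
        "fatigue"
      ],
      "prevention_options": [
        "anticoagulant"
      ],
      "risk_factors": [
        "hypertension",
        "af_fact_age"
      ],
      "treatment_options": [
        "warfarin",
        "rate_control"
      ]
    }
  }
}
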