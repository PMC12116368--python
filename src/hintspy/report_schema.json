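{
  "type": "object",
  "required": [
    "subject_id",
    "diagnosis_label",
    "triage",
    "predicted_group",
    "hints",
    "nystagmus",
    "impulses",
    "catch_up_counts",
    "vor_gain",
    "warnings",
    "config"
  ],
  "properties": {
    "subject_id": {"type": "string"},
    "diagnosis_label": {
      "type": "string",
      "enum": ["healthy", "peripheral", "central", "unknown"]
    },
    "triage": {
      "type": "string",
      "enum": ["peripheral-pattern", "central-pattern", "indeterminate"]
    },
    "predicted_group": {
      "type": "string",
      "enum": ["healthy", "peripheral", "central", "unknown"]
    },
    "hints": {
      "type": "object",
      "required": [
        "hit_abnormal",
        "hit_testable",
        "nystagmus_class",
        "triage",
        "evidence"
      ],
      "properties": {
        "hit_abnormal": {"type": "boolean"},
        "hit_testable": {"type": "boolean"},
        "nystagmus_class": {
          "type": "string",
          "enum": [
            "none",
            "unidirectional-horizontal",
            "direction-changing",
            "vertical"
          ]
        },
        "triage": {
          "type": "string",
          "enum": ["peripheral-pattern", "central-pattern", "indeterminate"]
        },
        "evidence": {"type": "object"}
      }
    },
    "nystagmus": {"type": "object"},
    "impulses": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "onset",
          "offset",
          "peak_time",
          "peak_angular_velocity",
          "direction",
          "adequate",
          "stage"
        ]
      }
    },
    "catch_up_counts": {"type": "object"},
    "skew": {"type": "object", "nullable": true},
    "vor_gain": {"type": "object"},
    "warnings": {"type": "array", "items": {"type": "string"}},
    "config": {
      "type": "object",
      "required": ["trim_seconds", "nominal_rate", "thresholds"]
    }
  }
}
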