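{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "fieldgaze QC report",
  "type": "object",
  "required": ["version", "protocol", "sessions"],
  "properties": {
    "version": {"type": "integer"},
    "protocol": {
      "type": "object",
      "properties": {
        "n_sessions": {"type": "integer"},
        "total_planned_min": {"type": "number"},
        "sessions": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["session_id", "planned_duration_min"],
            "properties": {
              "session_id": {"type": "string"},
              "planned_duration_min": {"type": "number"}
            }
          }
        }
      }
    },
    "sessions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["session_id", "errors"],
        "properties": {
          "session_id": {"type": "string"},
          "planned_duration_min": {"type": "number"},
          "errors": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["stage", "error"],
              "properties": {
                "stage": {"type": "string"},
                "error": {"type": "string"}
              }
            }
          },
          "alignment": {"type": "object"},
          "cleaning": {"type": "object"},
          "movement": {"type": "object"},
          "gaze_validation": {"type": "object"},
          "heading_validation": {"type": "object"},
          "pointing": {"type": "object"}
        }
      }
    }
  }
}
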