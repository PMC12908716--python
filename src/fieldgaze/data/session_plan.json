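{
  "description": "Study session plan: five exploration sessions across three days; the first three lasted 30 minutes, the final two were shortened to 20 minutes.",
  "sessions": [
    {"session_id": "1_1", "planned_duration_min": 30},
    {"session_id": "2_1", "planned_duration_min": 30},
    {"session_id": "3_1", "planned_duration_min": 30},
    {"session_id": "4_1", "planned_duration_min": 20},
    {"session_id": "5_1", "planned_duration_min": 20}
  ]
}
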