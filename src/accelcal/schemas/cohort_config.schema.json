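{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "accelcal cohort config",
  "description": "Parameters of the synthetic walking-bout cohort generator. All fields optional; omitted fields take the package defaults.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "n_participants": {"type": "integer", "minimum": 1},
    "speed_means_ms": {
      "description": "Mean walking speed (m/s) per condition: slow, normal, brisk.",
      "type": "array", "items": {"type": "number", "exclusiveMinimum": 0},
      "minItems": 3, "maxItems": 3
    },
    "speed_sds_ms": {
      "type": "array", "items": {"type": "number", "exclusiveMinimum": 0},
      "minItems": 3, "maxItems": 3
    },
    "count_model": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "v": {"$ref": "#/$defs/countModelParams"},
        "vm": {"$ref": "#/$defs/countModelParams"}
      },
      "required": ["v", "vm"]
    },
    "missing_bout_prob": {"type": "number", "minimum": 0, "maximum": 1},
    "seed": {"type": "integer"}
  },
  "$defs": {
    "countModelParams": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "intercept": {"type": "number"},
        "slope": {"type": "number", "exclusiveMinimum": 0},
        "participant_sd": {"type": "number", "minimum": 0},
        "epoch_sd": {"type": "number", "minimum": 0}
      },
      "required": ["intercept", "slope", "participant_sd", "epoch_sd"]
    }
  }
}
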