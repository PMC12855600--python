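{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ahusce parameter file",
  "type": "object",
  "required": ["parameters"],
  "properties": {
    "config": {
      "type": "object",
      "properties": {
        "starting_age": {"type": "number", "minimum": 0},
        "male_fraction": {"type": "number", "minimum": 0, "maximum": 1},
        "cycle_length_days": {"type": "number", "exclusiveMinimum": 0},
        "discount_rate": {"type": "number", "minimum": 0},
        "horizon_age": {"type": "number"},
        "half_cycle_correction": {"type": "boolean"},
        "wtp_grid": {"type": "array", "items": {"type": "number"}}
      },
      "additionalProperties": true
    },
    "parameters": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["mean"],
        "properties": {
          "mean": {"type": "number"},
          "se": {"type": ["number", "null"], "minimum": 0},
          "family": {"enum": ["beta", "gamma", "normal", "lognormal", "fixed"]},
          "units": {"type": "string"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
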