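{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pup-endotype night report",
  "type": "object",
  "required": ["metadata", "night", "per_window", "endogram", "surrogate_indices", "warnings"],
  "properties": {
    "metadata": {
      "type": "object",
      "required": ["version", "seed", "config"],
      "properties": {
        "version": {"type": "string"},
        "seed": {"type": "integer"},
        "config": {"type": "object"},
        "inputs": {"type": "object"}
      }
    },
    "night": {
      "type": "object",
      "required": ["traits", "ci95"],
      "properties": {
        "traits": {
          "type": "object",
          "required": ["vpassive", "vmin", "vactive", "compensation", "arousal_threshold", "lg1", "lgn"]
        },
        "ci95": {"type": "object"},
        "labels": {"type": ["object", "null"]},
        "cohort": {"type": ["string", "null"]}
      }
    },
    "per_window": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["t_start", "t_end", "traits", "fit"],
        "properties": {
          "t_start": {"type": "number"},
          "t_end": {"type": "number"},
          "traits": {"type": "object"},
          "fit": {
            "type": "object",
            "required": ["gain_G", "tau_s", "delay_s", "arousal_gamma", "sse", "n_fit_breaths", "identifiable"]
          },
          "flags": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "endogram": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["drive_median", "vent_median", "n"],
        "properties": {
          "drive_median": {"type": "number"},
          "vent_median": {"type": "number"},
          "n": {"type": "integer"}
        }
      }
    },
    "surrogate_indices": {
      "type": "object",
      "required": ["ahi", "f_hypopnea", "mean_oa_duration", "nrem_oai_over_nrem_ahi", "rem_ahi_over_nrem_ahi"]
    },
    "warnings": {"type": "array", "items": {"type": "string"}}
  }
}
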