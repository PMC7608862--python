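{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tremorkit subject report",
  "type": "object",
  "required": ["subject", "any_tremor", "frequency_bounds", "recordings", "params"],
  "properties": {
    "subject": {"type": "string"},
    "any_tremor": {"type": "boolean"},
    "frequency_bounds": {
      "type": "object",
      "required": ["f_l_hz", "f_u_hz", "n_peaks_used", "is_population_fallback"],
      "properties": {
        "f_l_hz": {"type": "number", "description": "lower subject tremor bound, Hz"},
        "f_u_hz": {"type": "number", "description": "upper subject tremor bound, Hz"},
        "j25_freq_hz": {"type": ["number", "null"], "description": "25th weighted-percentile peak frequency"},
        "j75_freq_hz": {"type": ["number", "null"], "description": "75th weighted-percentile peak frequency"},
        "n_peaks_used": {"type": "integer", "minimum": 0},
        "is_population_fallback": {"type": "boolean"}
      }
    },
    "recordings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["location", "task", "n_segments", "n_detected", "segments"],
        "properties": {
          "location": {"type": "string"},
          "task": {"type": "string"},
          "n_segments": {"type": "integer", "minimum": 0},
          "n_detected": {"type": "integer", "minimum": 0},
          "median_a_r_deg": {"type": ["number", "null"], "description": "median rotational amplitude over qualifying segments, degrees"},
          "max_a_r_deg": {"type": ["number", "null"]},
          "median_a_p_cm": {"type": ["number", "null"], "description": "median translational amplitude over qualifying segments, cm"},
          "max_a_p_cm": {"type": ["number", "null"]},
          "segments": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["time_s", "detected", "a_r_deg", "a_p_cm", "rho",
                           "source", "action_detected", "action_rms_cm"],
              "properties": {
                "time_s": {"type": "number", "description": "segment start time, s"},
                "detected": {"type": "boolean"},
                "tremor_freq_hz": {"type": ["number", "null"]},
                "a_r_deg": {"type": "number", "minimum": 0},
                "a_p_cm": {"type": "number", "minimum": 0},
                "rho": {"type": "number", "minimum": 0},
                "source": {"type": "string", "enum": ["", "acceleration", "rotational-velocity"]},
                "action_detected": {"type": "boolean"},
                "action_rms_cm": {"type": "number", "minimum": 0}
              }
            }
          }
        }
      }
    },
    "params": {"type": "object", "description": "full AlgorithmParams used for the run"}
  }
}
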