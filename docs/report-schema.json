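{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "alchest-report/1",
  "title": "alchest workflow report",
  "type": "object",
  "required": ["schema", "config", "estimators", "provenance"],
  "properties": {
    "schema": {"const": "alchest-report/1"},
    "config": {"type": "object"},
    "estimators": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["states", "delta_f", "d_delta_f",
                     "endpoint_delta_f", "endpoint_error", "units"],
        "properties": {
          "states": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["names", "values"],
              "properties": {
                "names": {"type": "array", "items": {"type": "string"}},
                "values": {"type": "array", "items": {"type": "number"}}
              }
            }
          },
          "delta_f": {"type": "array",
                      "items": {"type": "array", "items": {"type": "number"}}},
          "d_delta_f": {"type": "array",
                        "items": {"type": "array", "items": {"type": "number"}}},
          "endpoint_delta_f": {"type": "number"},
          "endpoint_error": {"type": "number", "minimum": 0},
          "units": {"enum": ["kT", "kJ/mol", "kcal/mol"]},
          "temperature": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "failures": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "decorrelation": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["window", "t0", "g", "n_effective", "n_kept"],
          "properties": {
            "window": {"type": "array", "items": {"type": "number"}},
            "t0": {"type": "integer", "minimum": 0},
            "g": {"type": "number", "minimum": 1},
            "n_effective": {"type": "number", "minimum": 0},
            "n_kept": {"type": "integer", "minimum": 0}
          }
        }
      }
    },
    "overlap": {
      "type": "object",
      "required": ["states", "matrix"],
      "properties": {
        "states": {"type": "array"},
        "matrix": {"type": "array",
                   "items": {"type": "array", "items": {"type": "number"}}}
      }
    },
    "convergence": {
      "type": "object",
      "required": ["fractions", "forward_df", "forward_err",
                   "backward_df", "backward_err"],
      "properties": {
        "fractions": {"type": "array", "items": {"type": "number"}},
        "forward_df": {"type": "array", "items": {"type": "number"}},
        "forward_err": {"type": "array", "items": {"type": "number"}},
        "backward_df": {"type": "array", "items": {"type": "number"}},
        "backward_err": {"type": "array", "items": {"type": "number"}}
      }
    },
    "equilibration": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["threshold", "windows"],
        "properties": {
          "threshold": {"type": "number"},
          "windows": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["window", "fraction_equilibration", "flagged"],
              "properties": {
                "window": {"type": "array", "items": {"type": "number"}},
                "fraction_equilibration": {"type": ["number", "null"]},
                "flagged": {"type": "boolean"},
                "error": {"type": ["string", "null"]}
              }
            }
          }
        }
      }
    },
    "ti_curvature": {
      "type": "object",
      "required": ["second_differences", "mean_curvature"],
      "properties": {
        "second_differences": {"type": "array",
                               "items": {"type": "number"}},
        "mean_curvature": {"type": "number"}
      }
    },
    "provenance": {"type": "object"}
  }
}
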