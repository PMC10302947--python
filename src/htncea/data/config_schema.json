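{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "htncea model configuration",
  "description": "Hierarchical parameter file for the four-state hypertension prevention cost-utility model. Costs are USD, rates per year. A 'param' is either a bare number (point value) or an object with a base-case value and/or an uncertainty distribution.",
  "type": "object",
  "required": ["transition", "hazards", "costs", "utilities", "compliance", "efficacy", "economics"],
  "$defs": {
    "distribution": {
      "type": "object",
      "minProperties": 1,
      "maxProperties": 1,
      "properties": {
        "beta": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}, "minItems": 2, "maxItems": 2},
        "triangular": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3, "description": "low <= mode <= high"},
        "point": {"type": "number"}
      },
      "additionalProperties": false
    },
    "param": {
      "oneOf": [
        {"type": "number"},
        {
          "type": "object",
          "properties": {
            "value": {"type": "number"},
            "dist": {"$ref": "#/$defs/distribution"},
            "assumption": {"type": "boolean"},
            "source": {"type": "string"}
          },
          "anyOf": [{"required": ["value"]}, {"required": ["dist"]}],
          "additionalProperties": false
        }
      ]
    },
    "hazard_block": {
      "type": "object",
      "required": ["normal", "pre", "stage1", "stage2", "mortality_immediate", "mortality_yearly"],
      "properties": {
        "normal": {"$ref": "#/$defs/param"},
        "pre": {"$ref": "#/$defs/param"},
        "stage1": {"$ref": "#/$defs/param"},
        "stage2": {"$ref": "#/$defs/param"},
        "mortality_immediate": {"$ref": "#/$defs/param"},
        "mortality_yearly": {"$ref": "#/$defs/param"}
      }
    },
    "state_map": {
      "type": "object",
      "required": ["normal", "pre", "stage1", "stage2"],
      "additionalProperties": {"type": ["number", "null"]}
    }
  },
  "properties": {
    "transition": {
      "type": "object",
      "required": ["normal_to_pre", "pre_to_stage1", "stage1_to_stage2", "pre_to_normal"],
      "additionalProperties": {"$ref": "#/$defs/param"},
      "description": "Annual transition probabilities; pre_to_stage1 + pre_to_normal must not exceed 1."
    },
    "hazards": {
      "type": "object",
      "required": ["ami", "stroke", "esrd"],
      "properties": {
        "ami": {"$ref": "#/$defs/hazard_block"},
        "stroke": {"$ref": "#/$defs/hazard_block"},
        "esrd": {"$ref": "#/$defs/hazard_block"}
      }
    },
    "costs": {
      "type": "object",
      "required": ["mi_admission", "mi_visit", "stroke_admission", "stroke_visit", "esrd_annual", "htn_admission", "htn_visit", "lifestyle_low", "lifestyle_mid", "lifestyle_full", "checkup_regular", "checkup_advanced", "screening", "terminal_care", "drug"],
      "additionalProperties": {"$ref": "#/$defs/param"}
    },
    "utilities": {
      "type": "object",
      "required": ["state", "complication"],
      "properties": {
        "state": {"$ref": "#/$defs/state_map"},
        "complication": {
          "type": "object",
          "required": ["ami", "stroke", "esrd"],
          "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
        },
        "combination_rule": {"enum": ["product", "minimum"]}
      }
    },
    "compliance": {
      "type": "object",
      "required": ["lifestyle", "screening", "medication"],
      "additionalProperties": {"$ref": "#/$defs/param"}
    },
    "efficacy": {
      "type": "object",
      "required": ["sbp_reduction"],
      "properties": {
        "sbp_reduction": {"$ref": "#/$defs/state_map"},
        "dbp_reduction": {"type": "object", "additionalProperties": {"type": ["number", "null"]}}
      }
    },
    "economics": {
      "type": "object",
      "required": ["discount_rate", "horizon_years", "initial_state_distribution"],
      "properties": {
        "discount_rate": {"$ref": "#/$defs/param"},
        "horizon_years": {"type": "integer", "minimum": 1},
        "initial_state_distribution": {"$ref": "#/$defs/state_map"}
      }
    },
    "care_model": {
      "type": "object",
      "properties": {
        "mi_visits_per_year": {"type": "number", "minimum": 0},
        "stroke_visits_per_year": {"type": "number", "minimum": 0},
        "htn_visits_per_year": {"type": "object", "additionalProperties": {"type": "number", "minimum": 0}},
        "htn_admissions_per_year": {"type": "object", "additionalProperties": {"type": "number", "minimum": 0}}
      }
    },
    "risk_model": {
      "type": "object",
      "properties": {
        "intercept": {"type": "number"},
        "modify_regression": {"type": "boolean"},
        "cutoffs": {"type": ["array", "null"], "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
        "covariates": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["distribution", "weight"],
            "properties": {
              "distribution": {"enum": ["normal", "bernoulli"]},
              "weight": {"type": "number"},
              "mu": {"type": "number"},
              "sigma": {"type": "number", "minimum": 0},
              "p": {"type": "number", "minimum": 0, "maximum": 1}
            }
          }
        }
      }
    },
    "strategies": {
      "type": "object",
      "description": "Optional per-strategy bundle overrides; see interventions module."
    }
  }
}
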