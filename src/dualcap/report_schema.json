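{
  "type": "object",
  "required": {
    "config": {
      "type": "object",
      "required": {
        "experiment": "integer",
        "accuracy_window": "array",
        "min_run_length": "integer",
        "n_boot": "integer",
        "seed": "integer",
        "first_response_only": "boolean"
      }
    },
    "exclusions": {
      "type": "object",
      "required": {
        "n_input": "integer",
        "n_fixation_break": "integer",
        "n_out_of_window": "integer",
        "n_kept": "integer",
        "excluded_runs": "array"
      }
    },
    "n_subjects": "integer",
    "aoc": {
      "type": "object",
      "required": {
        "group_means": "object",
        "model_tests": "object",
        "verdict": "object",
        "p_top": {
          "type": "object",
          "required": {
            "mean": "number",
            "ci_low": "number",
            "ci_high": "number"
          }
        },
        "side_asymmetry": "object",
        "first_response_only": "object"
      }
    },
    "tradeoff": {
      "type": "object",
      "required": {
        "n_flagged": "integer",
        "group_test": "object"
      }
    },
    "congruency": {
      "type": "object",
      "required": {
        "n_flagged_cells": "integer",
        "mean_effect": "object"
      }
    },
    "response_order": {
      "type": "object",
      "required": {
        "group_test": "object"
      }
    }
  }
}
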