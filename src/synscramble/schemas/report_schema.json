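{
  "$defs": {
    "AssociationRow": {
      "properties": {
        "effect": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Effect"
        },
        "n_deleted": {
          "title": "N Deleted",
          "type": "integer"
        },
        "n_retained": {
          "title": "N Retained",
          "type": "integer"
        },
        "p": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P"
        },
        "reason": {
          "default": "",
          "title": "Reason",
          "type": "string"
        },
        "segment": {
          "title": "Segment",
          "type": "string"
        },
        "significant": {
          "default": false,
          "title": "Significant",
          "type": "boolean"
        },
        "stat": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Stat"
        },
        "tested": {
          "default": true,
          "title": "Tested",
          "type": "boolean"
        }
      },
      "required": [
        "segment",
        "n_deleted",
        "n_retained"
      ],
      "title": "AssociationRow",
      "type": "object"
    },
    "ESRRow": {
      "properties": {
        "esr_reversed": {
          "title": "Esr Reversed",
          "type": "boolean"
        },
        "frac_iesr_up": {
          "title": "Frac Iesr Up",
          "type": "number"
        },
        "frac_resr_down": {
          "title": "Frac Resr Down",
          "type": "number"
        },
        "strain": {
          "title": "Strain",
          "type": "string"
        }
      },
      "required": [
        "strain",
        "frac_iesr_up",
        "frac_resr_down",
        "esr_reversed"
      ],
      "title": "ESRRow",
      "type": "object"
    },
    "PopulationSummary": {
      "properties": {
        "circular_pct": {
          "title": "Circular Pct",
          "type": "integer"
        },
        "event_fractions": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Event Fractions",
          "type": "object"
        },
        "linear_pct": {
          "title": "Linear Pct",
          "type": "integer"
        },
        "mean_events": {
          "title": "Mean Events",
          "type": "number"
        },
        "n_strains": {
          "title": "N Strains",
          "type": "integer"
        },
        "size_range_bp": {
          "additionalProperties": {
            "items": {
              "type": "integer"
            },
            "type": "array"
          },
          "title": "Size Range Bp",
          "type": "object"
        }
      },
      "required": [
        "n_strains",
        "mean_events",
        "circular_pct",
        "linear_pct",
        "event_fractions",
        "size_range_bp"
      ],
      "title": "PopulationSummary",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "package_version": {
          "title": "Package Version",
          "type": "string"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        }
      },
      "required": [
        "seed",
        "config_hash",
        "package_version"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "RegressionReport": {
      "properties": {
        "intercept": {
          "title": "Intercept",
          "type": "number"
        },
        "r": {
          "title": "R",
          "type": "number"
        },
        "r_pvalue": {
          "title": "R Pvalue",
          "type": "number"
        },
        "slope": {
          "title": "Slope",
          "type": "number"
        }
      },
      "required": [
        "r",
        "r_pvalue",
        "slope",
        "intercept"
      ],
      "title": "RegressionReport",
      "type": "object"
    }
  },
  "properties": {
    "association": {
      "items": {
        "$ref": "#/$defs/AssociationRow"
      },
      "title": "Association",
      "type": "array"
    },
    "esr": {
      "items": {
        "$ref": "#/$defs/ESRRow"
      },
      "title": "Esr",
      "type": "array"
    },
    "excluded_strains": {
      "items": {
        "type": "string"
      },
      "title": "Excluded Strains",
      "type": "array"
    },
    "n_excluded_ploidy": {
      "title": "N Excluded Ploidy",
      "type": "integer"
    },
    "population": {
      "$ref": "#/$defs/PopulationSummary"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    },
    "retention_recovery": {
      "$ref": "#/$defs/RegressionReport"
    },
    "top_association_segment": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Top Association Segment"
    }
  },
  "required": [
    "provenance",
    "population",
    "n_excluded_ploidy",
    "excluded_strains",
    "retention_recovery",
    "association",
    "esr"
  ],
  "title": "RunReport",
  "type": "object"
}
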