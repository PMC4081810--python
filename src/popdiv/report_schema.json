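{
  "type": "object",
  "required": ["report_version", "stages_run"],
  "properties": {
    "report_version": {"type": "integer"},
    "stages_run": {"type": "array", "items": {"type": "string"}},
    "seq": {
      "type": "object",
      "required": ["n_samples", "length", "loci", "n_haplotypes", "populations"],
      "properties": {
        "n_samples": {"type": "integer"},
        "length": {"type": "integer"},
        "n_haplotypes": {"type": "integer"},
        "loci": {
          "type": "array",
          "items": {"type": "object", "required": ["name", "start", "end"]}
        },
        "populations": {"type": "array", "items": {"type": "string"}}
      }
    },
    "popgen": {
      "type": "object",
      "required": ["diversity", "between", "amova", "neutrality"],
      "properties": {
        "diversity": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["population", "n", "k", "h", "pi"]
          }
        },
        "between": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["pop_x", "pop_y", "dxy_percent", "da_percent"]
          }
        },
        "amova": {
          "type": "object",
          "required": ["phi", "p", "df_among", "df_within", "n_perm"],
          "properties": {
            "phi": {"type": "number"},
            "p": {"type": "number"}
          }
        },
        "neutrality": {"type": "object"}
      }
    },
    "demography": {
      "type": "object",
      "required": ["mismatch", "generation_time"],
      "properties": {
        "generation_time": {"type": "number"},
        "mismatch": {"type": "object"}
      }
    },
    "network": {
      "type": "object",
      "required": ["connection_limit", "n_observed", "n_edges", "n_components"],
      "properties": {
        "connection_limit": {"type": "integer"},
        "n_observed": {"type": "integer"},
        "n_inferred": {"type": "integer"},
        "n_edges": {"type": "integer"},
        "n_components": {"type": "integer"}
      }
    },
    "niche": {
      "type": "object",
      "required": ["lineages", "kept_variables", "variance_explained", "axes"],
      "properties": {
        "axes": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["axis", "observed", "background", "null_lo", "null_hi", "verdict"]
          }
        }
      }
    },
    "morph": {"type": "object"}
  }
}
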