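{
  "type": "object",
  "required": ["seed", "alpha", "stages", "report_version", "artifacts"],
  "properties": {
    "seed": {"type": "integer"},
    "alpha": {"type": "number"},
    "report_version": {"type": "integer"},
    "stages": {"type": "array", "items": {"type": "string"}},
    "artifacts": {"type": "object"},
    "extinct": {"type": "boolean"},
    "genomics": {
      "type": "object",
      "required": ["n_snps", "n_pruned_retained", "pc_variance_fractions"],
      "properties": {
        "n_snps": {"type": "integer"},
        "n_pruned_retained": {"type": "integer"},
        "pc_variance_fractions": {"type": "array", "items": {"type": "number"}}
      }
    },
    "gwas": {
      "type": "object",
      "required": ["lambda_gc", "threshold", "n_tests", "n_significant", "top_snp", "top_snp_p"],
      "properties": {
        "lambda_gc": {"type": "number"},
        "threshold": {"type": "number"},
        "n_tests": {"type": "integer"},
        "n_significant": {"type": "integer"},
        "top_snp": {"type": "string"},
        "top_snp_p": {"type": "number"},
        "top_snp_is_causal": {"type": "boolean"},
        "heritability": {"type": "number"}
      }
    },
    "concordance": {
      "type": "object",
      "required": ["counts", "fraction"],
      "properties": {
        "counts": {"type": "object"},
        "fraction": {"type": "number"}
      }
    },
    "demography": {"type": "object"},
    "selection": {"type": "object"},
    "components": {"type": "object"},
    "candidate_region": {
      "type": "object",
      "required": ["scaffold", "n_tests", "threshold", "top_snp"],
      "properties": {
        "scaffold": {"type": "string"},
        "n_tests": {"type": "integer"},
        "threshold": {"type": "number"},
        "top_snp": {"type": "string"},
        "top_snp_p": {"type": "number"},
        "n_significant": {"type": "integer"}
      }
    }
  }
}
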