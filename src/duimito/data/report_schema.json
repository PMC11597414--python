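{
  "type": "object",
  "required": ["provenance", "genomes", "composition", "divergence",
               "dnds", "cox2", "ur_table", "gene_order", "patterns"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package", "version", "seed", "config_hash", "thresholds"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "seed": {"type": ["number", "null"]},
        "config_hash": {"type": "string"},
        "thresholds": {"type": "object"}
      }
    },
    "genomes": {"type": "array", "items": {"type": "object",
      "required": ["id", "species", "sex_type", "length"]}},
    "composition": {"type": "array", "items": {"type": "object",
      "required": ["genome", "scope"]}},
    "divergence": {"type": "array", "items": {"type": "object",
      "required": ["species", "scope"]}},
    "dnds": {"type": "array", "items": {"type": "object",
      "required": ["species", "gene"]}},
    "cox2": {"type": "array", "items": {"type": "object",
      "required": ["species", "genome", "kind"]}},
    "ur_table": {"type": "array", "items": {"type": "object",
      "required": ["genome", "flanks", "length"]}},
    "gene_order": {"type": "array", "items": {"type": "object",
      "required": ["species", "breakpoint_distance"]}},
    "patterns": {"type": "object"}
  }
}
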