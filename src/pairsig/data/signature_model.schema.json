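{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pairsig SignatureModel",
  "type": "object",
  "required": ["provenance", "cutoff", "pairs"],
  "properties": {
    "provenance": {"enum": ["published", "trained"]},
    "cutoff": {"type": "number"},
    "pairs": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["gene1", "gene2", "weight"],
        "properties": {
          "gene1": {"type": "string"},
          "gene2": {"type": "string"},
          "weight": {"type": "number"}
        }
      }
    },
    "metadata": {"type": "object"}
  }
}
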