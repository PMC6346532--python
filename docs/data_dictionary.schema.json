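{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "snr data dictionary",
  "description": "Declares the dimensions (columns) of a differential-expression table. Exactly one dimension must have kind 'identifier' and be named 'EnsemblID'. Dimension names must be unique and non-empty. Additional top-level fields are preserved as opaque metadata.",
  "type": "object",
  "required": ["dimensions"],
  "properties": {
    "dimensions": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "kind"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "kind": {"enum": ["numeric", "categorical", "identifier"]},
          "description": {"type": "string"}
        }
      }
    }
  },
  "additionalProperties": true
}
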