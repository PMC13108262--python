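{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "metacure template dialect",
  "description": "Reference description of the simplified structured-template JSON dialect. Enforcement happens via the package's pydantic models; this file documents the on-disk shape.",
  "type": "object",
  "required": ["name", "fields"],
  "properties": {
    "name": {"type": "string", "minLength": 1},
    "provenance": {"type": "string"},
    "fields": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "description": {"type": "string"},
          "datatype": {"enum": ["string", "integer", "date"]},
          "required": {"type": "boolean"},
          "permissible_values": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["term"],
              "properties": {
                "term": {"type": "string", "minLength": 1},
                "vocabulary": {"type": "string"},
                "term_id": {"type": "string"},
                "frequency": {"type": "number", "minimum": 0, "maximum": 1}
              }
            }
          }
        }
      }
    }
  }
}
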