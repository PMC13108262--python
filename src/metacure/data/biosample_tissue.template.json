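{
  "name": "biosample_tissue",
  "provenance": "Structured template for human sample metadata; tissue terms pre-materialized from an anatomy-ontology branch (UBERON), usage frequencies observed over curated submissions.",
  "fields": [
    {
      "name": "organism",
      "description": "Scientific binomial name of the sampled organism.",
      "datatype": "string",
      "required": true
    },
    {
      "name": "tissue",
      "description": "Anatomical tissue the sample derives from; standardized anatomy term.",
      "datatype": "string",
      "required": true,
      "permissible_values": [
        {"term": "blood", "vocabulary": "UBERON", "term_id": "UBERON:0000178", "frequency": 0.50},
        {"term": "lung", "vocabulary": "UBERON", "term_id": "UBERON:0002048", "frequency": 0.15},
        {"term": "liver", "vocabulary": "UBERON", "term_id": "UBERON:0002107", "frequency": 0.15},
        {"term": "ovary", "vocabulary": "UBERON", "term_id": "UBERON:0000992", "frequency": 0.15},
        {"term": "plasma", "vocabulary": "UBERON", "term_id": "UBERON:0001969", "frequency": 0.03},
        {"term": "lymph", "vocabulary": "UBERON", "term_id": "UBERON:0002391", "frequency": 0.02},
        {"term": "kidney", "vocabulary": "UBERON", "term_id": "UBERON:0002113"},
        {"term": "brain", "vocabulary": "UBERON", "term_id": "UBERON:0000955"},
        {"term": "heart", "vocabulary": "UBERON", "term_id": "UBERON:0000948"}
      ]
    },
    {
      "name": "isolate",
      "description": "Identification or description of the specific individual from which this sample was obtained.",
      "datatype": "string",
      "required": false
    },
    {
      "name": "age",
      "description": "Age of the organism at sampling, in years.",
      "datatype": "integer",
      "required": false
    },
    {
      "name": "sex",
      "description": "Phenotypic sex of the sampled organism.",
      "datatype": "string",
      "required": false,
      "permissible_values": [
        {"term": "female", "vocabulary": "PATO", "term_id": "PATO:0000383"},
        {"term": "male", "vocabulary": "PATO", "term_id": "PATO:0000384"}
      ]
    }
  ]
}
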