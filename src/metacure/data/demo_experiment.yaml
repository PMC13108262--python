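# Demo experiment: synthetic corpus, baseline vs dictionary-guided vs
# template-guided correction, six runs of the stochastic mock backend.
seed: 7
runs: 6
queries:
  - "tissue:lung"
  - "tissue:blood"
  - "tissue:liver"
  - "tissue:ovary"
synthetic:
  n_records: 600
  seed: 7
  disease_name_swap: 0.6
  synonym_variant: 0.3
  verbose_freetext: 0.2
conditions: [baseline, dd, cedar]
backend: mock
error_rate: 0.1
malformed_rate: 0.0
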