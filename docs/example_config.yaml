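# Example configuration overrides (see config_schema.json for all keys).
# Use with: cgsynapse simulate --preset fig2 --config docs/example_config.yaml
n_steps: 2000000
record_stride: 20000
affinities:
  trans_ctla4_b7: -7.0
  dimer_b7: -7.0
  trans_pd1_pdl1: -7.0
  cis_b7_pdl1: -7.0
copy_numbers:
  CTLA4_DIMER: 200
  B7: 200
  PD1: 0
  PDL1: 0
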