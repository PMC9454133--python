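# Demo pipeline configuration (same settings as tracm7g.demo_config()).
# Run:  tracm7g run --config examples/demo_config.yaml --outdir demo_run
seed: 7
simulate:
  n_trnas: 30
  n_modified: 8
  reads_per_library: 6000
  n_genes: 200
  depth_per_library: 200000
codon:
  n_perm: 500
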