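# End-to-end demo: small synthetic study, one chromosome.
seed: 7
simulation:
  n_genes: 24
  n_tes: 12
  n_lncrnas: 16
  n_clusters: 12
  chrom_length: 600000
  n_meth_bins: 30
  n_acrs: 6
  n_decoys_per_replicate: 3
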