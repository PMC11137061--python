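# Small end-to-end demonstration run (completes in well under a minute).
out_dir: scratch/demo_run
seed: 42
sim:
  genome_size_mb: 10.0
  n_sites_standing: 300
  ems_rate_per_mb: 2.7
  n_founders: 15
  n_populations: 4
  pop_size: 40
  n_generations: 8
generations: [3, 7]
pheno_pairing: {3: 4, 7: 8}
n_embryos: 20
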