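# Demo analysis configuration: two synthetic case/control cohorts with a
# shared causal architecture, a measured protein panel, and a scale-free
# PPI carrying a planted disease module.
out_dir: results/pipeline_run
seed: 1
b_norm: 500
b_perm: 10000
cohort:
  n_samples: 2000
  n_variants: 240
  n_blocks: 12
  rho: 0.7
  maf_range: [0.05, 0.5]
  n_causal_disease: 8
  h2_liability: 0.3
  prevalence: 0.1
  n_proteins: 40
  cis_effect_sd: 0.4
  trans_effect_sd: 0.15
  noise_sd: 1.0
  n_ppi_nodes: 300
  planted_module_size: 12
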