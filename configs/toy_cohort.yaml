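# Bundled toy cohort: two-cohort family sample (600 discovery + 300
# replication), 5,000 gene-dropped markers, 10 proteins with heritabilities
# spanning 0.2-0.78, cis effects up to ~27% of variance, an age effect up to
# ~27%, rare medication indicators, cohort batch shifts and below-LOD
# censoring on two proteins.
seed: 1
outdir: pqtlkit_run
synthetic:
  n_families: 130
  offspring_per_family: 4
  n_singletons: 120
  cohort_split: 0.6666666666666666
  n_markers: 5000
  n_proteins: 10
  genotype_missing_rate: 0.002
  abo_missing_rate: 0.005
qc:
  min_protein_obs: 200
  max_below_lod_fraction: 0.75
  lod_n_sd: 3.0
covariates:
  alpha: 0.05
genotype_qc:
  marker_call_rate: 0.95
  individual_call_rate: 0.98
  hwe_alpha: 0.05
  min_mac: 1
gwas:
  alpha: 0.05
  conditional_cutoff: 5.0e-8
  min_mac: 3
cutoffs:
  min_group_size: 10
  central: 0.95
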