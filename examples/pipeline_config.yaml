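# Small end-to-end configuration for `famgs run`.
# Ten additive causal SNPs jointly explain ~12% of liability; the shared
# sibling component brings family clustering to autism-like recurrence.
output_dir: famgs_demo
seed: 11

simulate:
  n_families_discovery: 200
  n_families_validation: 150
  n_snps: 500
  children_per_family: [2, 4]
  maf_range: [0.05, 0.5]
  shared_sib_var: 0.35
  male_prevalence: 0.0185185     # 1/54
  female_prevalence: 0.0039683   # 1/252
  ascertainment_min_affected: 2
  causal:
    - {index: 0, model: additive, beta: 0.169, maf: 0.3}
    - {index: 1, model: additive, beta: 0.169, maf: 0.3}
    - {index: 2, model: additive, beta: 0.169, maf: 0.3}
    - {index: 3, model: additive, beta: 0.169, maf: 0.3}
    - {index: 4, model: additive, beta: 0.169, maf: 0.3}
    - {index: 5, model: dominant, beta: 0.24, maf: 0.3}
    - {index: 6, model: dominant, beta: 0.24, maf: 0.3}
    - {index: 7, model: recessive, beta: 0.40, maf: 0.4}
    - {index: 8, model: recessive, beta: 0.40, maf: 0.4}
    - {index: 9, model: additive, beta: 0.169, maf: 0.3}

evidence:
  p_true: 0.9        # favourable-evidence probability, causal-SNP genes
  p_false: 0.05      # ... null-SNP genes

qc:
  hwe_p_min: 1.0e-3
  call_rate_min: 0.90
  maf_min: 0.05

selection:
  p_family_max: 1.0e-3
  p_sibling_max: 0.05

scoring:
  cutoff: 4.0
  proximal_bp: 5000
  extended_bp: 50000

liability:
  male: {K: 0.0185185, K_R: 0.1205}   # K_R consistent with the simulated sharing
  female: {K: 0.0039683, K_R: 0.0589}

evaluation:
  ascertainment_correction: true
  min_affected: 2
  mc_target_children: 20000

bootstrap:
  B: 200
  enabled: true
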