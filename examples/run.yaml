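# Four-cohort synthetic study at the real cohorts' sample sizes.
# Run with:  stoichsi run-all --config examples/run.yaml --out results/run1
seed: 7
simulate:
  n_genes: 54
  cohorts: [[71, 165], [35, 93], [73, 75], [125, 142]]
  delta: 2.0
  imbalance_rate_lambda: 3.0
cohort_names: [cmc_hbcc, cmc_pitt, braingvex_smri, bipseq_sacc]
gene_set: all          # or a locus-to-gene TSV path to apply the L2G rules
plans:                 # modelling-set sizes mirror the study's splits
  cmc_hbcc: {model_size: 94, iterations: 50}
  cmc_pitt: {model_size: 69, iterations: 50}
  braingvex_smri: {model_size: 67, iterations: 50}
  bipseq_sacc: {model_size: 93, iterations: 50}
si:
  iterations: 50       # fallback for cohorts without an explicit plan
  n_lambda: 12         # LASSO path resolution
  n_folds: 10
thresholds:
  l2g: 0.5
  tie_tolerance: 0.05
  imbalance: 2.0
  fdr: 0.05
  prevalence: 0.02
control_analyses: true # case-modelling swap + control-split null on cohort 0
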