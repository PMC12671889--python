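# Example end-to-end run on a simulated cohort.
# Every key shown is validated; unknown keys are rejected.
#
#   holdoutcca fit --config examples/config.yaml --out results_example
#
# To analyze real data instead of simulating, replace `simulate:` with
#   data_dir: path/to/dir   # containing X.csv, Y.csv, confounds.csv
#                           # (and optionally geometry.csv)

simulate:
  n_subjects: 1000
  n_risk_factors: 20
  n_parcels: 40
  planted_dims:
    - canonical_correlation: 0.5
      x_weight_smoothness: 0.5
      y_block_pattern: [3.0, 0.0]   # loads the first risk-factor block
  rf_blocks:
    - {size: 6, within_correlation: 0.6}   # body-composition-like block
    - {size: 5, within_correlation: 0.6}   # air-pollution-like block
  marker_dim_index: 0
  marker_spearman_target: -0.39

scaling_mode: raw            # raw | proportional | corrected
sample_mode: mixed           # mixed | women | men (sex-stratified subsample)
marker_column: marker

# multiple-holdout scheme
n_outer: 5
n_inner: 5
holdout_frac: 0.2
test_frac: 0.2

# shared regularization grid for the RCCA
grid: [0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99]

n_perm: 1000                 # permutations per outer split
n_perm_spin: 1000            # spin permutations for annotation batteries
alpha: 0.05
max_dimensions: 3
seed: 0
out_dir: results_example
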