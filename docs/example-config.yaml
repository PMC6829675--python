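# Reduced demonstration configuration for `connfuse run`.
# Omitted keys fall back to the package defaults (full study scale:
# 83/94 subjects, 100 CV rounds, 10,000 permutations).
cohort:
  n_group_A: 40
  n_group_B: 40
  episode_counts: {depressive: 14, manic: 12, remission: 14}
  planted_edges:
    - [31, 23, -0.2, 0.2, 0.25]
    - [32, 23, -0.2, 0.2, 0.25]
    - [31, 24, -0.2, 0.2, 0.25]
    - [32, 24, -0.2, 0.2, 0.25]
  couple_structural: true
qc:
  n_discard: 10
  fd_threshold_mm: 0.5
  global_sd_threshold: 2.0
  exclusion_fraction: 0.2
  band_hz: [0.01, 0.08]
permutation:
  n_perm: 1000
cv:
  n_rounds: 10
  n_folds: 10
  inner_folds: 3
  grid: [1.0, 21.0, 41.0]
  k: 4
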