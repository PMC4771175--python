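# Toy synthetic-study configuration: small enough to run every stage in
# seconds while exercising all 13 inference methods end to end.
seed: 42
n_antibodies: 12
density: 0.0929
cohort_sizes:
  C1: 80
  C2: 80
  C3: 80
noise_sd: 0.1
edge_rescale_fraction: 0.3
recall_max: 0.1
top_k: 6
threshold_candidates:
  start: 5
  stop: 61
  step: 5
n_edge_groups: 3
n_modules: 4
genelists:
  n_lists: 30
  n_top_level: 6
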