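# Small synthetic demo panel for the one-shot pipeline.
seed: 42
simulate:
  n_strains: 6
  n_core: 60
  n_dispensable: 40
  n_unique_per_strain: 5
  n_traits: 4
  causal_cluster_size: 2
  hgt_block_count: 2
  hgt_block_size: 5
  paralog_frac: 0.1
  mobile_frac: 0.05
  spurious_hit_rate: 0.01
families:
  max_evalue: 1.0e-4
  min_identity: 50.0
  min_cov_frac: 0.5
  inflation: 1.8
pangenome:
  n_permutations: 200
  exhaustive_max: 6
gc:
  high_threshold: 68.0
  low_threshold: 49.0
  max_gap_genes: 5
  min_genes: 5
traits:
  od_cutoff: 0.3
  mode: exact
consensus:
  threshold: 0.5
  n_trees: 60
  perturb_prob: 0.1
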