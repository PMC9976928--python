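bin_width: 1.0
boundary_slop: 30
downstream_bp: 1000
flank_size: 2000
max_evalue: 1.0e-100
merge_gap: 200
min_aa: 300
min_coverage: 0.4
min_hit_identity: 0.0
min_identity: 0.8
n_groups: 8
n_random: 5000
promoter_bp: 1000
random_mode: uniform
seed: 7
spacer23: 35
synthetic:
  bursts:
  - - 0.01
    - 8
    - 1.0
  - - 0.12
    - 8
    - 0.75
  genome_length: 300000
  n_chroms: 2
  n_genes: 24
  n_sites: 600
  n_states: 4
  site_genic_fold: 2.0
target_halfwidth: 10
tss_bin: 100
tss_halfwidth: 3000
young_threshold: 0.02
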