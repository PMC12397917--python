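# Demo run configuration for `milletpop pipeline`.
# One global seed is expanded into per-stage seeds; rerunning with the same
# config is bit-identical.
seed: 2024

demography:
  L: 3000            # simulated biallelic sites
  n_chrom: 1
  N_wild: 500
  N_cult: 100
  split_gen: 60      # generations since domestication
  outgroup_gen: 300  # generations since outgroup divergence
  n_cult_samples: 150
  n_out_samples: 10
  hitch_alpha: 5.0e-6   # broad sweep footprint (~100 kb scale)

sweeps:
  - locus_pos: 750000
    s_beneficial: 0.5

filter:
  max_missing_rate: 0.7   # VCFtools --max-missing (keep threshold)
  min_gq: 10
  min_maf: 0.01

window:
  snps_per_window: 50
  step_snps: 51

clr:
  grid_bp: 20000

pam:
  n_families: 2000

traits:
  n_causal: 50
  h2: [0.5, 0.5]
  r_g: 0.5

flank_bp: 50000

gwas_trait:        # oligogenic trait used for the association scan
  n_causal: 5
  h2: 0.8
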