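# Desk-scale pipeline configuration (the package defaults, spelled out).
# Pass to any CLI verb with --config.
n_train: 300          # prior-predictive training simulations per model
ns: 100               # selected summary statistics per model
rf_trees: 200         # trees per random forest
n_particles: 200      # ABC-SMC particles per generation
n_generations: 5
smc_quantile: 0.5     # next tolerance = this quantile of accepted distances
min_acceptance: 0.02
n_replicates: 10      # replicates per synthetic test-case

domains:
  ac: {lattice_resolution: 33, n_initial_tips: 5, n_timesteps: 200, dt: 1.0}
  sl: {lattice_resolution: 33, n_initial_tips: 5, n_timesteps: 300, dt: 0.05}
  ps: {lattice_resolution: 33, n_initial_tips: 5, n_timesteps: 300, dt: 1.0}

settings:
  vegf_profile: linear
  fibronectin_dynamic: true
  branch_probability: 1.0
  max_tips: 128

feature_config:
  image_resolution: 10      # persistence-image pixels per side
  # image_bandwidth defaults to side_length / 20
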