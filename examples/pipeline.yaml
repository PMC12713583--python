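# Annotated pipeline configuration (all values shown are the defaults).
# Run with:  stnpop run --config examples/pipeline.yaml --outdir out/

seed: 0                       # master seed for every stochastic stage

input:
  simulate: true              # generate a synthetic campaign; otherwise read:
  spikes: null                #   tidy spike table (neuron_id, trial_id, spike_time_ms)
  trials: null                #   trial table (see README schema)

simulate:
  n_neurons_per_cluster: [8, 8, 8]      # planted profile sizes
  n_trials_per_condition: 6             # per scene x value x direction cell

stages:                       # toggle any stage off to skip it
  clustering: true
  pca_validation: true
  encoding: true
  sliding_glm: true
  trajectories: true
  decoding: true

clustering:
  k_range: [2, 6]             # candidate K for silhouette selection
  n_repeats: 100              # k-means repeats per K (5000 = full procedure)

encoding:
  epoch_ms: [100, 300]        # post-target window for condition means
  n_boot: 199                 # parametric-bootstrap iterations (10000 = full)

decoding:
  k_outer: 4                  # outer grouped folds (10 = full procedure)
  k_inner: 3                  # inner grouped folds for lambda selection
  n_lambdas: 6                # glmnet-style grid below lambda_max (50 = full)
  max_iter: 200               # saga iterations per fit

window_ms: [-600, 600]        # target-aligned analysis window (1-ms bins)
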