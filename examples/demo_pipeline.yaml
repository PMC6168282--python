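# End-to-end demo: synthesize a stratified survey, then run every stage.
out_dir: scratch/demo_out
seed: 11
scenario:
  n_sites_per_cell: 4
  n_days: 21
  species:
    - name: coyote
      occ_intercept: 0.3      # logit scale; ~0.57 baseline occupancy
      det_intercept: -0.9     # ~0.29 daily detection probability
      occ_coefs: {core_forest_5km: 0.5}
      event_rate: 0.08        # independent detection events per camera-night
    - name: red_fox
      occ_intercept: -0.4
      det_intercept: -1.1
      occ_coefs: {yard: 0.7}
      event_rate: 0.05
    - name: deer
      occ_intercept: 1.0
      det_intercept: -0.3
      event_rate: 0.3
species: [coyote, red_fox]    # species entering the occupancy model
occ_covariates: [core_forest_5km]
mcmc: {warmup: 300, iters: 300}
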