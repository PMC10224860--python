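# Annotated configuration for `vhit run --config examples/run_config.yaml --out OUT`.
# Every key is optional; unknown keys are rejected so typos cannot silently
# fall back to defaults. The seed here can be overridden with --seed.

seed: 1

trace:                        # per-session vHIT simulation
  sampling_rate: 220          # Hz, eye/head tracker rate
  n_impulses_per_direction: 10
  noise_sd: 5.0               # deg/s white noise on the eye channel
  vor_latency: 0.0            # s; the gain window applies no compensation
  saccade_probability: 0.2    # chance of a catch-up saccade per impulse
  impulse_duration: 0.15      # s, raised-cosine pulse length
  peak_velocity_range: [150.0, 220.0]   # deg/s, uniform sampling range
  min_quiescence: 0.5         # s of rest between impulses
  # duration: 30.0            # fix the trace length (capacity-checked)

cohort:                       # study cohort simulation
  pre_post_correlation: 0.7   # correlation of repeated gain measures
  mssq_nausea_coupling: 0.6   # latent coupling of MSSQ and nausea ranks

detection:                    # impulse detector thresholds
  search_threshold: 50        # deg/s, triggers an event
  onset_threshold: 20         # deg/s, backtracking target for the onset
  refractory: 0.5             # s, suppresses double detections
  max_rise_time: 0.1          # s, onset backtracking horizon

stats:
  alpha: 0.05
  pooling: direction-mean     # or all-impulses
  power_n_grid: [10, 15, 20]  # total sample sizes for the power curve
  power_reps: 1000            # Monte-Carlo replicates per grid point
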