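n_sessions: 60
seed: 0
fs: 250.0
af_fraction: 0.096
phys:
  resting_vo2: 3.9
  vo2_gain: 0.1545595054095827
  vt_vo2_mean: 14.0
  vt_vo2_sd: 4.5
  peak_vo2_mean: 21.8
  peak_vo2_sd: 7.4
  vslope_below: 0.85
  vslope_above: 1.25
  rq_rest: 0.95
  ve_vco2_gain: 30.2
  rcp_ve_factor: 1.4
  rcp_fraction: 0.6
  hr_rest: 75.0
  hr_peak: 136.0
  hr_vt_frac: 0.46
  hrv_below: 0.06
  hrv_above: 0.012
  hrv_freq: 0.25
  rr_jitter_sd: 0.005
  af_mode: false
  af_rr_cv: 0.15
  breath_noise_sd: 0.25
split_fractions:
- 0.373
- 0.277
- 0.35
network:
  conv_blocks:
  - - 8
    - 7
    - 10
  - - 16
    - 17
    - 5
  - - 24
    - 9
    - 4
  lstm_units: 24
  dense_units: 16
  covariate_merge_point: post_lstm
  epochs: 20
  learning_rate: 0.002
  weight_decay: 0.0001
  batch_size: 64
  seed: 0
  input_length: 7500
  n_covariates: 3
  scale_preset: desk_scale
  dtype: float32
dlt_threshold: 0.5
dlt_k: 1
exercise_time_mode: window_start
out_dir: experiment_out
log_level: INFO
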