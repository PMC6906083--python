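# Default pipeline configuration.  Every value can be overridden by a user
# config file or command-line flags; alarm thresholds/delays are monitor
# settings and deliberately configurable.
seed: 0

simulate:
  n_infants: 20
  duration_s: 21600        # 6 h per infant
  event_rate_per_h: 8.0
  precursor_lead_s: 60.0
  precursor_spo2_drop: 4.0
  precursor_hr_drop: 6.0
  brady_coupling_prob: 0.3
  missing_rate: 0.01
  burst_missing_rate: 0.0005
  burst_length_s: 20.0
  nn_artifact_rate: 0.002
  thresholds:
    spo2_low_yellow: 88.0
    spo2_low_red: 80.0
    hr_low_yellow: 100.0
    hr_low_red: 80.0
    hr_high_yellow: 200.0
    hr_high_red: 220.0
    delay_s: 10.0
    spo2_averaging_s: 8.0

windows:                   # [pre_s, post_s] pairs to analyse
  - [120, 60]

split:
  frac: 0.8
  k: 5

model:
  spec_target: 0.98
  tol: 0.001
  max_subset_size: 8
  n_rounds: 200
  learning_rate: 0.1
  min_per_class: 50

projection:                # printed study-scale inputs; override at will
  yellow_total: 278000
  red_total: 70000
  n_ytnr: 232823
  red_in_ytr: 56415
  sensitivity: 0.33
  specificity: 0.98
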