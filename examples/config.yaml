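# Full-run configuration for `qeeg run-all -c examples/config.yaml`.
# Every key is optional; anything omitted keeps the package default.

scenario:
  seed: 1
  subject_variability_sd: 0.2
  # amplitudes are linear multipliers on unit-variance band noise;
  # pink_floor scales the broadband 1/f background
  stage_profiles:
    baseline:        {delta_amp: 1.0, theta_amp: 0.7,  alpha_amp: 0.9,  beta_amp: 0.5,  pink_floor: 0.3}
    induction_start: {delta_amp: 0.8, theta_amp: 0.7,  alpha_amp: 1.1,  beta_amp: 0.7,  pink_floor: 0.3}
    loc:             {delta_amp: 2.0, theta_amp: 0.5,  alpha_amp: 0.45, beta_amp: 0.25, pink_floor: 0.3}
    intubation:      {delta_amp: 1.3, theta_amp: 0.33, alpha_amp: 0.3,  beta_amp: 0.17, pink_floor: 0.2}
    preincision:     {delta_amp: 1.4, theta_amp: 0.45, alpha_amp: 0.5,  beta_amp: 0.25, pink_floor: 0.25}
    incision:        {delta_amp: 2.2, theta_amp: 0.4,  alpha_amp: 0.3,  beta_amp: 0.22, pink_floor: 0.25}
  stage_durations:  # seconds; must tile into 4-s epochs
    baseline: 60
    induction_start: 8
    loc: 8
    intubation: 8
    preincision: 8
    incision: 4

n_subjects: 19
alpha: 0.05
fdr: false

preprocess:
  band_low: 0.5      # Hz
  band_high: 35.0    # Hz
  epoch_seconds: 4
  outlier_k: 3.0     # robust-SD units
  filter_order: 4

features:
  apen_m: 2
  apen_r_factor: 0.2
  wavelet_name: db4
  boundary_mode: periodization

output_dir: qeeg_output
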