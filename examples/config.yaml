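# Example generator configuration for `vwmlab simulate` / `vwmlab report`.
# Omitted fields keep their defaults (see vwmlab.config).
seed: 11
n_subjects: 10
trials_per_cell: 100
capacity_k:
  homogeneous: 2.2
  heterogeneous: 3.0
mixture_truth:
  pT: 0.7
  pN: 0.15
  pU: 0.15
  kappa: 12.0
eeg:
  sfreq: 250.0
  noise_sd: 10.0
  pink_noise_frac: 0.5
  cda_amp_by_load:
    1: -0.5
    3: -1.5
    5: -1.5
  bilateral_effect_amp: -1.0
  saccade_rate: 0.05
  blink_rate: 0.05
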