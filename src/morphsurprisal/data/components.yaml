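# Default evoked-component configuration for the response simulator.
#
# Four components: an occipital response around 100 ms, an
# occipito-temporal letter-string response around 150 ms, and sustained
# left/right temporal responses around 400 ms. Window amplitudes are
# linear in the listed standardized predictors; trial noise is calibrated
# at simulation time so the planted model R² matches `target_r2` unless
# `trial_noise_sd` is set explicitly.
#
# Per-participant gain is lognormal(0, gain_sigma) and offset is
# normal(0, offset_sd) in nAm. No study reports per-participant amplitude
# variance directly; these two values are conventions chosen to motivate
# the within-participant z-scoring stage, not measured quantities.
epoch_ms: [-200, 800]
sampling_rate_hz: 1000
components:
  occipital:
    peak_latency_ms: 100
    window_ms: [80, 120]
    baseline_nAm: 15.0
    betas:
      length: 0.30
    target_r2: 0.09
    offset_sd: 1.0
    gain_sigma: 0.2
  occipito_temporal:
    peak_latency_ms: 150
    window_ms: [140, 200]
    baseline_nAm: 20.0
    betas:
      length: -0.15
      bigram_surprisal_bits: -0.14
    target_r2: 0.04
    offset_sd: 1.0
    gain_sigma: 0.2
  left_temporal:
    peak_latency_ms: 400
    window_ms: [300, 700]
    baseline_nAm: 25.0
    betas:
      image_complexity: -0.15
      mdl_surprisal_bits: 0.22
      surface_surprisal_bits: 0.22
    target_r2: 0.15
    offset_sd: 1.0
    gain_sigma: 0.2
  right_temporal:
    peak_latency_ms: 400
    window_ms: [300, 700]
    baseline_nAm: 20.0
    betas:
      image_complexity: -0.24
      length: 0.33
      mdl_surprisal_bits: 0.21
    target_r2: 0.12
    offset_sd: 1.0
    gain_sigma: 0.2
behavior:
  rt_baseline_ms: 852.0
  rt_betas:
    length: 0.36
    bigram_surprisal_bits: -0.11
    mdl_surprisal_bits: 0.20
    lemma_surprisal_bits: 0.14
    surface_surprisal_bits: 0.21
  target_r2: 0.52
  rt_scale_ms: 95.0
  accuracy_mean: 0.92
  accuracy_sd: 0.04
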