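group: BmtTwiH
weight_mean_g: 10.0
weight_sd_g: 1.6
sensor_noise_sd_gf: 0.1
seed: null
tremor:
  mode: blunted
  f0: 14.0
  half_width: 5.0
  amplitude_pct: 2.2
  narrow_f0: 12.2
  narrow_amplitude_pct: 0.4
locomotion:
  speed_mean: 10.0
  speed_sd: 5.0
  pause_prob: 0.4
  pause_dwell_s: 5.0
  heading_sd: 0.2
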