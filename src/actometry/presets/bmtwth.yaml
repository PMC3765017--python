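group: BmtWtH
weight_mean_g: 15.5
weight_sd_g: 1.8
sensor_noise_sd_gf: 0.1
seed: null
tremor:
  mode: blunted
  f0: 12.5
  half_width: 3.5
  amplitude_pct: 1.8
  narrow_f0: 12.2
  narrow_amplitude_pct: 0.4
locomotion:
  speed_mean: 12.0
  speed_sd: 6.0
  pause_prob: 0.35
  pause_dwell_s: 4.0
  heading_sd: 0.2
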