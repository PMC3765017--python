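group: Wt
weight_mean_g: 16.9
weight_sd_g: 1.8
sensor_noise_sd_gf: 0.1
seed: null
tremor:
  mode: broadband
  f0: 5.0
  half_width: 2.5
  amplitude_pct: 1.0
  narrow_f0: 12.2
  narrow_amplitude_pct: 0.0
locomotion:
  speed_mean: 40.0
  speed_sd: 15.0
  pause_prob: 0.05
  pause_dwell_s: 2.0
  heading_sd: 0.2
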