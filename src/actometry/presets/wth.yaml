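group: WtH
weight_mean_g: 16.9
weight_sd_g: 1.8
sensor_noise_sd_gf: 0.1
seed: null
tremor:
  mode: narrowband
  f0: 12.2
  half_width: 0.25
  amplitude_pct: 4.0
  narrow_f0: 12.2
  narrow_amplitude_pct: 0.0
locomotion:
  speed_mean: 10.0
  speed_sd: 5.0
  pause_prob: 0.4
  pause_dwell_s: 5.0
  heading_sd: 0.2
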