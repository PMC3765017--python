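group: Twi
weight_mean_g: 10.4
weight_sd_g: 1.6
sensor_noise_sd_gf: 0.1
seed: null
tremor:
  mode: broadband
  f0: 15.8
  half_width: 3.0
  amplitude_pct: 2.0
  narrow_f0: 12.2
  narrow_amplitude_pct: 0.0
locomotion:
  speed_mean: 15.0
  speed_sd: 8.0
  pause_prob: 0.25
  pause_dwell_s: 4.0
  heading_sd: 0.2
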