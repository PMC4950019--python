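adapt_duration_flicker: 6.0
adapt_duration_outline: 4.0
background: 0.5
battery_px_per_deg: 5.0
criterion_fraction: 0.1
dipole:
  alpha: 0.05
  beta: 0.3
  drive_gain: 10.0
  out_threshold: 0.05
  tonic: 0.2
dt: 0.005
fill:
  block: 500.0
  couple: 800.0
  decay: 0.02
  input_gain: 5.0
half_period: 0.25
px_per_deg: 10.0
sample_every: 0.25
source_surround_sigma: 3.0
test_contrast: 0.05
test_duration: 2.0
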