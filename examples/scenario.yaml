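# Example synthetic dual-instrument survey scenario.
# A sparse accurate "primary" instrument (12 points), a dense positively
# biased "secondary" instrument (100 points, 12 co-located with primary),
# and 11 independent validation points, on a 300 m x 240 m domain.
domain:
  x_min: 0.0
  y_min: 0.0
  cell_size: 10.0
  n_cols: 30
  n_rows: 24
field_model:
  model: gaussian
  nugget: 0.02
  sill: 0.32        # total sill (sill_is_total defaults to true)
  range: 70/35
  direction: 115
mean_log_level: 5.0
sources:
  - {x: 90.0, y: 170.0, amplitude: 3.0, decay_length: 45.0}
  - {x: 210.0, y: 120.0, amplitude: 2.5, decay_length: 35.0}
n_primary: 12
n_secondary: 100
n_validation: 11
n_colocated: 12
primary_noise_sd_log: 0.05
secondary_slope: 1.4
secondary_intercept: 30.0
secondary_noise_sd: 0.10
seed: 20160330
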