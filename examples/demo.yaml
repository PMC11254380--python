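calling:
  blank_floor: 30
constants:
  avogadro: 6.02214076e+23
  droplet_volume_pl: 65.0
  duration_min: 240.0
  frame_interval_min: 30.0
  threshold_multiplier: 3.29
dynamics:
  k: 2.3263813101037414
  rho: 0.75
panel:
  channel_map:
    ch1: IL-6
    ch2: TNF-a
    ch3: IFN-g
  panel_id: panel1
simulation:
  baseline_mean: 100.0
  baseline_sd: 10.0
  calibration:
    IFN-g:
      c_max: 500.0
      form: linear
      parameters:
        gain_nm_per_au: 0.05
    IL-6:
      c_max: 500.0
      form: linear
      parameters:
        gain_nm_per_au: 0.05
    TNF-a:
      c_max: 500.0
      form: linear
      parameters:
        gain_nm_per_au: 0.05
  cell_loading: 0.3
  n_droplets: 10000
  pattern_fractions:
  - 0.4
  - 0.4
  - 0.2
  rate_lognormal:
  - 3.4011973816621555
  - 1.5
  secretor_fraction: 0.08
  seed: 7
  sigma_blk: 5.0
  window_mode: uniform
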