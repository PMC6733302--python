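material:
  name: Lactohale 200
geometry: {}
scan:
  acquisition_rate: 15.0
  rotation_speed: 3.83
  n_waveforms: 2000
  time_window: 45.0
  noise_sigma: 0.0015
stages:
  pressures:
  - 0.0
  - 2.0
  - 4.0
  - 6.0
  - 8.0
  n_runs: 3
  heterogeneity_amp: 0.01
processing:
  filter_window: 5
  datum_threshold: 0.5
  n_bins: 230
  max_rotations: 7
  artifact_angles: []
dosing:
  deficit: auto
  hole_width: null
  positions: null
  stage: last
  depth_threshold: 0.015
  map_bins: 230
weights:
  dosator_diameter_mm: 3.4
  chamber_length_mm: 5.0
  efficiency: 1.5
  noise_sd_mg: 0.8
caliper_noise_sd_mm: 0.1
seed: 1
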