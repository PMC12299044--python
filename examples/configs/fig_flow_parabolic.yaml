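# Color Doppler of a carotid-style vessel phantom, parabolic flow peaking at
# 1.0 m/s: 256-element array, 2.5 MHz four-cycle transmit / one-cycle
# receive, fs 20 MHz, five plane-wave angles x 10 acquisitions at
# fPRF 5 kHz, 4 dB magnitude cutoff, 1.54 x 1.57 mm Hamming smoothing.
# Full scale is 50k + 50k scatterers; pass --scale 0.1 for desk runs.
mode: doppler
seed: 0
fs_hz: 20.0e6
array: {n_elements: 256, width_m: 0.3e-3, height_m: 7.0e-3, kerf_m: 0.05e-3}
excitation: {f0_hz: 2.5e6, n_cycles: 4, rx_n_cycles: 1}
medium: {c_m_s: 1540.0, rho_kg_m3: 1000.0}
phantom:
  type: vessel
  n_scatterers: 50000       # moving
  n_static: 50000
  region_m: [[-0.030, 0.030], [-0.005, 0.005], [0.010, 0.080]]  # static box
  vessel_radius_m: 0.005
  vessel_angle_deg: 45.0
  vessel_center_m: [0.0, 0.0, 0.040]
  flow_profile: parabolic
  peak_speed_m_s: 1.0
plane_wave:
  angles_deg: [-6.0, -3.0, 0.0, 3.0, 6.0]
doppler:
  fprf_hz: 5000.0
  frames_per_angle: 10
  cutoff_db: 4.0
  smooth_height_m: 1.54e-3
  smooth_width_m: 1.57e-3
beamforming:
  x_m: [-0.020, 0.020, 0.1569e-3]
  z_m: [0.010, 0.080, 0.001]
  f_number: 1.5
  dynamic_range_db: 60.0
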