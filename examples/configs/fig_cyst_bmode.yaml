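# B-mode imaging of the cyst/point-target phantom: walking 64-element
# Hanning-apodized sub-aperture focused at 60 mm on transmit, with
# six fixed receive foci (35..85 mm).  Pass --scale for desk-scale runs.
mode: bmode
seed: 0
fs_hz: 16.0e6
array: {n_elements: 128, width_m: 0.3e-3, height_m: 7.0e-3, kerf_m: 0.05e-3}
excitation: {f0_hz: 3.0e6, n_cycles: 1}
medium: {c_m_s: 1540.0, rho_kg_m3: 1000.0}
phantom:
  type: cyst
  n_scatterers: 100000
  region_m: [[-0.025, 0.025], [-0.005, 0.005], [0.030, 0.090]]
  default_features: true
bmode:
  n_subaperture: 64
  focus_depth_m: 0.060
  receive_foci_m: [0.035, 0.045, 0.055, 0.065, 0.075, 0.085]
beamforming:
  x_m: [-0.0224, 0.0224, 0.175e-3]
  z_m: [0.030, 0.090, 0.001]
  f_number: 2.0
  dynamic_range_db: 60.0
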