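# Plane wave imaging of the cyst/point-target phantom with coherent
# compounding over five steering angles in [-6, +6] degrees.
mode: pw
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
plane_wave:
  angles_deg: [-6.0, -3.0, 0.0, 3.0, 6.0]
beamforming:
  x_m: [-0.0224, 0.0224, 0.175e-3]
  z_m: [0.030, 0.090, 0.001]
  f_number: 2.0
  dynamic_range_db: 60.0
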