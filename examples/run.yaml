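# Example run configuration: sphere geometry, beam, phantom, table build.
sphere:
  sphere_diameter: 150.0
  wall_reflectance: 0.97
  port_diameters:
    sample: 25.0
    reflection: 20.0
    normalization: 20.0
    detection: 20.0
  detector_view_diameter: 6.0

beam:
  incidence_angle: 8.0
  beam_radius: 2.5
  port_radius: 12.5

lut:
  mua_min: 1.0e-3
  mua_max: 0.3
  n_mua: 12
  musp_min: 1.0
  musp_max: 8.0
  n_musp: 12
  g: 0.75
  n_sample: 1.41
  thickness_d: 2.0
  photons: 20000

phantom:
  musp_600: 4.0
  dye_concentration: 4.0   # wt%
  thickness_d: 2.0

noise:
  shot_noise: true
  dark_rate: 50.0
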