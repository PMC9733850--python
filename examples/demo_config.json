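{
  "seed": 1,
  "out_dir": "scratch/demo_run",
  "multilayer": {
    "n_layers": 4,
    "lipids_per_layer": 2500,
    "amplitude": 13.18,
    "wavelength": 200.0,
    "segments": 50
  },
  "scattering": {
    "peaks": [[1.5141, 0.061003, 100.0]],
    "background": [2.0, 0.0],
    "q_min": 1.2,
    "q_max": 1.8
  },
  "adhesion": {
    "n": 12,
    "gamma": 0.22,
    "E_mpa": 42.0,
    "strains": [0.05, 0.10, 0.14],
    "rel_noise": 0.10
  },
  "topography": {
    "nx": 512,
    "ny": 512,
    "pixel_size": 10.0,
    "wrinkle_amplitude": 6.2225,
    "wrinkle_wavelength": 640.0
  }
}
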