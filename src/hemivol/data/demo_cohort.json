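{
  "n_subjects": 6,
  "seed": 11,
  "asat_range": [500, 900],
  "vat_range": [80, 220],
  "asat_left_frac": [0.508, 0.012, 0.482, 0.537],
  "vat_left_frac": [0.564, 0.025, 0.514, 0.659],
  "scoliosis_amplitude": [0.0, 3.0],
  "phantom": {
    "nx": 64,
    "ny": 64,
    "dx": 4.0,
    "dy": 4.0,
    "n_slices": 10,
    "outer": [100, 70],
    "inner": [60, 42],
    "taper": 0.08,
    "vat_blob_inplane": [8, 20],
    "vat_blob_axial": [12, 25],
    "vat_margin": 8.0,
    "fat_level": 1000,
    "lean_level": 100,
    "noise_sd": 30
  }
}
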