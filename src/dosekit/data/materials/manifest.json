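{
  "air": {
    "density_g_cm3": 0.001205
  },
  "water": {
    "density_g_cm3": 1.0
  },
  "soft_tissue": {
    "density_g_cm3": 1.06
  },
  "adipose": {
    "density_g_cm3": 0.95
  },
  "bone": {
    "density_g_cm3": 1.92
  },
  "lung": {
    "density_g_cm3": 0.26
  },
  "brain": {
    "density_g_cm3": 1.04
  },
  "aluminum": {
    "density_g_cm3": 2.699
  },
  "copper": {
    "density_g_cm3": 8.96
  }
}
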