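{
  "comment": "Spherical coordinates (latitude, longitude, radians) of the 8 occipito-parietal 10-20 sites on a unit-radius spherical head model, derived from the standard 10-05 montage.",
  "r": 1.0,
  "channels": {
    "O1":  {"lat": 0.075900, "lon": -1.826635},
    "O2":  {"lat": 0.075679, "lon": -1.310741},
    "Oz":  {"lat": 0.126887, "lon": -1.569860},
    "Pz":  {"lat": 0.794555, "lon": -1.566793},
    "P3":  {"lat": 0.532362, "lon": -2.163023},
    "P4":  {"lat": 0.531135, "lon": -0.954331},
    "PO7": {"lat": 0.024948, "lon": -2.083037},
    "PO8": {"lat": 0.024288, "lon": -1.052571}
  }
}
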