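[
  {
    "name": "lactate",
    "lineshape": "lorentzian",
    "peaks": [
      {"center": 1.310, "relative_area": 0.375, "linewidth": 0.004},
      {"center": 1.330, "relative_area": 0.375, "linewidth": 0.004},
      {"center": 4.090, "relative_area": 0.0625, "linewidth": 0.004},
      {"center": 4.102, "relative_area": 0.0625, "linewidth": 0.004},
      {"center": 4.114, "relative_area": 0.0625, "linewidth": 0.004},
      {"center": 4.126, "relative_area": 0.0625, "linewidth": 0.004}
    ]
  },
  {
    "name": "creatine",
    "lineshape": "lorentzian",
    "peaks": [
      {"center": 3.030, "relative_area": 0.6, "linewidth": 0.004},
      {"center": 3.930, "relative_area": 0.4, "linewidth": 0.004}
    ]
  },
  {
    "name": "glycine",
    "lineshape": "lorentzian",
    "peaks": [
      {"center": 3.550, "relative_area": 1.0, "linewidth": 0.004}
    ]
  },
  {
    "name": "choline",
    "lineshape": "lorentzian",
    "peaks": [
      {"center": 3.190, "relative_area": 0.75, "linewidth": 0.004},
      {"center": 3.510, "relative_area": 0.125, "linewidth": 0.004},
      {"center": 4.050, "relative_area": 0.125, "linewidth": 0.004}
    ]
  },
  {
    "name": "phosphocholine",
    "lineshape": "lorentzian",
    "peaks": [
      {"center": 3.210, "relative_area": 0.75, "linewidth": 0.004},
      {"center": 3.580, "relative_area": 0.125, "linewidth": 0.004},
      {"center": 4.160, "relative_area": 0.125, "linewidth": 0.004}
    ]
  },
  {
    "name": "myo-inositol",
    "lineshape": "lorentzian",
    "peaks": [
      {"center": 3.270, "relative_area": 0.167, "linewidth": 0.004},
      {"center": 3.520, "relative_area": 0.333, "linewidth": 0.004},
      {"center": 3.610, "relative_area": 0.333, "linewidth": 0.004},
      {"center": 4.050, "relative_area": 0.167, "linewidth": 0.004}
    ]
  }
]
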