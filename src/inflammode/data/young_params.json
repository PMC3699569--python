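{
  "schema": "inflammode-params-v1",
  "label": "young-baseline-v1",
  "note": "Engineering defaults for the young baseline: chosen for a stable resting state, post-LPS peak ordering TNF < IL-6 < NO2-/NO3-, and damage resolution within 24 h. Decay constants seeded from half-life reasoning (TNF fastest, NO slowest). Not fitted to animal data.",
  "parameters": {
    "kpe": 0.015,
    "kmpe": 0.014,
    "xmpe": 0.5,
    "kmd": 0.02,
    "xmd": 0.5,
    "km6": 0.01,
    "xm6": 4000.0,
    "kma": 0.007,
    "Mmax": 1.0,
    "knpe": 0.04,
    "xnpe": 0.5,
    "kn": 0.01,
    "Nmax": 1.0,
    "hn10": 5.0,
    "x10l": 80.0,
    "kinosm": 0.002,
    "kinosn": 0.025,
    "kdinos": 0.004,
    "knono": 0.1,
    "kno": 0.001,
    "kcpm": 40.0,
    "kcp": 0.012,
    "xcp6": 6000.0,
    "hcp6": 2.0,
    "xcp10": 300.0,
    "hcp10": 2.0,
    "s6": 0.06,
    "k6m": 150.0,
    "k6n": 100.0,
    "k6cp": 3.0,
    "x6cp": 200.0,
    "h6cp": 2.0,
    "k6no": 1.5,
    "x6no": 30.0,
    "kd6": 0.009,
    "s10": 0.15,
    "k10m0": 6.0,
    "k10cp": 4.0,
    "x10cp": 250.0,
    "h10cp": 8.0,
    "k10": 0.015,
    "kdn": 0.002,
    "xdn": 0.5,
    "kdd": 0.01
  }
}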