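{
  "_comment": "SYNTHETIC placeholder tissue relaxation values. These are NOT measured cadaveric-tissue properties; they are plausible stand-ins so the contrast-simulation pipeline runs end to end. Replace this file with measured (T1, T2, M0) values for the tissues of interest before drawing any conclusions about real contrast.",
  "tissues": [
    {"label": "synthetic myocardium", "t1_ms": 900.0, "t2_ms": 45.0, "m0": 1.0},
    {"label": "synthetic s.c. fat", "t1_ms": 380.0, "t2_ms": 110.0, "m0": 1.0}
  ]
}
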