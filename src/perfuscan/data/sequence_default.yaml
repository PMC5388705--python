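# Default RF-spoiled gradient-echo protocol for contrast simulation.
te_ms: 5.0
tr_ms: 20.0
flip_deg: {start: 0, stop: 90}   # integer flip angles, inclusive
n_spins: 100
n_excitations: 100
rf_phase_increment_deg: 117.0
phase_schedule: quadratic
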