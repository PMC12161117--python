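# Small synthetic demo: bdeeg run-all --config examples/demo.yaml --out demo
mode: synthetic
seed: 2
n_bd: 5
n_hc: 5
duration: 18.0
paradigms: [eyes_closed, eyes_open]
bands: [delta, beta]
cv_splits: 2
cv_repeats: 1
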