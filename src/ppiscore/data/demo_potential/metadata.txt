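alpha=1.0
corpus_hash=0f6be080f2cd77e9
g_floor=0.1
kappa=1.0
n_structures=80
note=demo potential derived from bundled synthetic fixtures; NOT the published interface matrices
threshold_d=4.0
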