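# 17-frame sequence for the tracker-noise sweep (one cell; nu set per run)
n_frames: 17
kind: circular
laps: 0.34
radius_mm: 40.0
seed: 0
nu: 1.0
sigma_v: 1.0
n_points: 50
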