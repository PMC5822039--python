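# 62-frame sequence with twelve frames blacked out
n_frames: 62
kind: circular
laps: 1.24
radius_mm: 40.0
seed: 0
nu: 1.0
sigma_v: 1.0
n_points: 50
blank_indices: [7, 11, 12, 23, 24, 37, 38, 42, 43, 45, 51, 54]
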