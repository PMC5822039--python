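# 150-frame circular sequence with nu = 1 tracker noise and 1 px visual noise
n_frames: 150
kind: circular
laps: 3.0
radius_mm: 40.0
seed: 0
nu: 1.0
sigma_v: 1.0
n_points: 50
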