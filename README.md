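# emtmosaic

Drift-free sequential mosaicking of an approximately planar scene by fusing
frame-to-frame visual correspondences with per-frame 6-DOF pose measurements
from an electromagnetic tracker (EMT).

## The problem

In fetoscopic laser surgery for twin-to-twin transfusion syndrome, the
surgeon must map vascular anastomoses on the placenta through an endoscope
with a tiny field of view. Stitching the video into a mosaic expands the
view, but purely visual mosaicking chains pairwise homographies
`H_j = H_{j,j-1} · ... · H_{2,1}`, so every registration error propagates:
the mosaic *drifts*, and a single unregistrable frame breaks the chain. An
EMT sensor at the scope tip measures the camera pose directly — noisy
("jittery") but *unbiased*, which makes it the ideal complement: visual
matches give precise relative registration, the tracker pins down the
absolute placement.

## The model

The scene is a plane with scaled normal `π = n/d` (n the unit normal, d the
camera-to-plane distance) in the frame of a virtual reference camera whose
image plane is the mosaic space. A camera pose is a minimal 6-vector
`x = [r, t]` (axis-angle rotation, translation), and induces the restricted
homography

    H = K (R − t πᵀ) K⁻¹,   R = exp(r),

mapping mosaic pixels to that camera's pixels. The estimate of all poses `X`
and the plane `π` maximizes the posterior given tracker measurements
`Z = {z_k}` and matched point sets, equivalently minimizes

    C(X, π) = C_v + C_EMT + C_p

where `C_v` sums weighted squared reprojection residuals of every
correspondence through `H_l H_m⁻¹`, `C_EMT` is the per-axis Mahalanobis
distance `Σ_k (z_k − x_k)ᵀ Σ_EMT⁻¹ (z_k − x_k)`, and `C_p` is a
constant-velocity motion prior
`Σ_k (x_k − μ_p(x_{k-1}, x_{k-2}))ᵀ Σ_p⁻¹ (·)` with
`μ_p` decomposed from `T_{k-1} T_{k-2}⁻¹ T_{k-1}`. The problem is solved by
damped Gauss–Newton (Levenberg–Marquardt).

Three estimators expose this, scikit-learn style (`fit` + fitted
attributes, `get_params`/`set_params`):

| estimator | method |
|---|---|
| `PairwiseChainMosaicker` | chained pairwise DLT homographies — the drifting vision-only baseline |
| `BundleAdjustmentMosaicker` | batch joint optimization; `use_emt=False` gives classical visual bundle adjustment (gauge-fixed), `use_emt=True` adds the tracker and prior terms |
| `SlidingWindowMosaicker` | sequential local bundle adjustment: per iteration only the `χe` newest cameras (and the plane) are estimated, `χg = W − χe` recent cameras are fixed in the window, and K-means–selected spatial *anchor* runs of already-fixed cameras contribute visual residuals that give the plane long-baseline support |

A synthetic-scene module (`emtmosaic.synthetic`) generates the full study
conditions — circular or handheld trajectories over a procedural planar
texture, tracker noise scaled by a multiplier ν around a base of 1°/1 mm,
correspondences with σ_v pixel noise, black-frame dropout — so everything is
testable without external data. `emtmosaic.evaluate` implements the drift
metric (mean mosaic-space discrepancy `e_j` of a 100×100 projected grid per
frame, averaged into `e_M`) and the scripted experiments;
`emtmosaic.render` builds the actual mosaic image by inverse warping and
feathered blending.

## Worked example

Chained pairwise registration drifts; the windowed fusion does not:

```python
from emtmosaic.evaluate import run_drift_experiment, DriftConfig

res = run_drift_experiment(DriftConfig(n_frames=150, nu=1.0, sigma_v=1.0, seed=1))
for name in ("pairvis", "lba_vis_emt"):
    slope, p = res.slopes[name]
    print(f"{name:12s} e_M = {res.e_M[name]:6.2f} px   "
          f"slope = {slope:+.4f} px/frame (p = {p:.2g})   bounded = {res.bounded[name]}")
```

prints

```
pairvis      e_M =  14.74 px   slope = +0.1439 px/frame (p = 2.1e-33)   bounded = True
lba_vis_emt  e_M =   8.37 px   slope = +0.0006 px/frame (p = 0.94)   bounded = True
```

The pairwise chain's per-frame error grows by ~0.14 px per frame
(significantly positive slope — that is drift); the sliding-window fusion's
error stays flat (slope indistinguishable from zero) and its level is set by
the tracker noise, not by the sequence length.

There is also a CLI for running the pipeline from a shell:

```sh
emtmosaic simulate --config examples/syn_drift.yaml --out run/
emtmosaic mosaic   --data run/ --out run/mosaic/
emtmosaic evaluate --homographies run/mosaic/homographies.csv \
                   --ground-truth run/gt_homographies.csv --out run/ej.csv
```

File formats are plain text throughout: poses/EMT as CSV
(`frame, rx, ry, rz, tx, ty, tz`; radians, mm), intrinsics as JSON/YAML
(`fx, fy, cx, cy`), the plane as JSON (`{"pi": [...]}` in 1/mm),
homographies as row-major 9-column CSV, correspondences as
`m, l, xa, ya, xb, yb` CSV.

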