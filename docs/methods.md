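# Methods

## Geometric model and conventions

The scene is modeled as a single plane. In the frame of a *virtual reference
camera* at the origin (whose image plane is the mosaic space Ω_M), the plane
is parametrized by the scaled normal `π = n/d` with units 1/mm, where `n` is
the unit normal pointing from the plane toward the camera and `d > 0` is the
camera-to-plane distance; on-plane 3-D points satisfy `πᵀp = 1`. Encoding
the inverse depth in each component keeps the induced homography nearly
linear in the plane parameters, which helps convergence.

A camera pose is the minimal 6-vector `x = [r, t]`: an axis-angle rotation
vector `r ∈ so(3)` (radians, `|r| < π`, which holds for scope motion that
never completes a full axial turn) and a translation `t` (mm). The pose
induces the plane-restricted homography

    H = K (R − t πᵀ) K⁻¹,   R = exp(r),

which maps mosaic pixels to the camera's pixels; consistently, the rigid map
from the reference frame to the camera frame is `X_cam = R X − t`
(extrinsics `[R | −t]`, camera center `Rᵀt`). Stitching uses `H⁻¹`. The
pairwise map from image m to image l is `H_l H_m⁻¹`. Pixels are 0-based,
origin top-left, x right / y down. Homographies are stored scale-canonical:
Frobenius norm 1, bottom-right entry positive (largest-magnitude entry
positive as fallback), and the canonicalization returns already-canonical
input unchanged bit-for-bit.

For reporting, the plane is also expressed as (azimuth, elevation, distance)
with azimuth = atan2(n_y, n_x) and elevation = asin(n_z), in degrees. This
convention is declared here and used consistently; nothing else depends on
it.

## Probabilistic model

Estimation is maximum a posteriori over all poses X and the plane π given
tracker measurements Z and matched point sets, assuming

1. a planar scene;
2. each tracker measurement is Gaussian about the true pose,
   `z_k ~ N(x_k, Σ_EMT)` with diagonal Σ_EMT, the rotation part expressed
   additively on the rotation-vector components;
3. each matched point in the target image is Gaussian about the projection
   of its source point, `p_B ~ N(μ_v, σ_v² I)` with
   `μ_v = proj(H_l H_m⁻¹ p̃_A)`;
4. a second-order Markov (constant-velocity) prior
   `x_k ~ N(μ_p(x_{k-1}, x_{k-2}), Σ_p)` with
   `μ_p` decomposed from `T̄ = T_{k-1} T_{k-2}⁻¹ T_{k-1}`.

Taking −2 log posterior gives the cost `C_v + C_EMT + C_p`; each term is
implemented as a weighted residual block whose stacked sum of squares equals
the cost exactly (verified by an independent-summation test).

**Visual residuals in pixel space.** Points are conceptually normalized via
`K⁻¹` and re-projected through `K`, so residuals are in pixels and
`σ_v = 1 px` is directly meaningful. This is equivalent to working in
normalized coordinates up to a fixed per-axis weighting.

**Correspondence-count normalization.** Landmarks are modeled independent
but correlated in reality, so many matches over-weight the visual term. The
`normalization` policy divides each pair's squared cost by a factor `c`:
`"none"` (c = 1, the literal MAP — correct when landmarks really are
independent, as in this package's simulator), `"per-pair-count"`
(c = N_pair, the default: every pair contributes the same total weight
regardless of match count), or `"global-count"` (c = total match count).

## Noise-model defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| σ_v | 1 | px | typical subpixel matcher accuracy; also the simulator's default |
| Σ_EMT | diag((1°)², …, (1 mm)², …) | rad², mm² | conservative tracker accuracy for a 6-DOF EM sensor; the simulator's base noise |
| Σ_p | diag((0.5°)², …, (1 mm)², …) | rad², mm² | calibrated on a held-out simulated trajectory via `estimate_motion_sigma` (per-frame second differences of the default circular/handheld motions are ≲0.6 mm, ≲0.3°) |

In experiments where the data's noise multiplier ν is known, the estimator's
Σ_EMT is scaled to match (`ν·1°`, `ν·1 mm` per axis). At ν = 0 the σ's are
clamped to 1e-4 (deg/mm): a pure numerical guard for the degenerate
zero-noise limit, small enough that the induced bias (the prior's
equilibrium pull against an exact measurement) is below 1e-7 mm.

## Solver

All solves use `scipy.optimize.least_squares` (damped Gauss–Newton /
Levenberg–Marquardt, `trf` variant with `x_scale='jac'` to handle the
radian/mm scale gap), finite-difference Jacobians, ftol = xtol = gtol =
1e-12, and at most 100 outer iterations. The EMT measurements initialize the
poses. If an accepted solution somehow exceeded the initial cost the initial
state would be returned (descent is also asserted in tests).

**Gauge.** With the tracker term the problem is fully constrained. Without
it (visual-only bundle adjustment) the monocular gauge is fixed by clamping
pose 0 to the identity (the initialization is first re-expressed relative to
frame 0 so this is consistent) and clamping the plane depth to its initial
value by optimizing only the normal's two direction angles.

**Plane initialization.** Default `π₀ = (0, 0, 1/100)`: fronto-parallel at
100 mm, a generic endoscopic working-distance guess. The visual term is
close to linear in π at fixed poses, so the solve is insensitive to this
choice (verified: identical optimum from d₀ ∈ {40, …, 100} mm).

## Sequential estimation (sliding window)

Window bookkeeping follows `W = χe + χg`: each iteration estimates the χe
newest cameras and the plane; the χg most recent previously-estimated
cameras participate as fixed constants (including two boundary
constant-velocity terms linking the new cameras to them); older cameras are
out of the window and untouched. Defaults W = 5, χe = 3, K = 3 anchor
clusters of 5 consecutive frames — the configuration used for the synthetic
sequences throughout.

* **Cold start.** The first window is solved as one batch. No pose is
  clamped: the tracker term fixes the gauge, and leaving the problem
  unmodified means that with `W = χe = N` the sequencer reduces *exactly* to
  batch visual+EMT adjustment (asserted to |Δe_M| < 0.1 px, measured 0).
* **Anchors.** A short temporal window has too little baseline to hold the
  plane depth, so each iteration projects the footprint centroids of all
  fixed cameras into the mosaic, clusters them with (seeded) K-means, and
  draws one seeded-random consecutive run per cluster, clipped to cluster
  membership. Anchor pairs contribute visual residuals only (their poses
  are fixed; only the plane is constrained). Window↔anchor pairs whose
  predicted footprints overlap are also requested — on revisits these act
  as weak loop closures. Correspondences for any requested pair come from a
  pluggable provider: a precomputed collection, the SIFT+RANSAC frontend on
  frames, or the simulator's on-demand generator (each pair drawn from its
  own seeded stream, so results are independent of request order).
* **Missing visual data.** A window with no usable pairs keeps the plane
  fixed and estimates its cameras from the tracker and motion-prior terms
  alone; a solver failure falls back to the raw measurements for that
  window and is logged. The pipeline never aborts on missing visual
  content.
* **Homography composition.** Each frame's mosaic homography is composed
  from its pose and the plane estimate *of the iteration that fixed it* and
  is not recomposed when the plane later moves; this is the sequential,
  streaming-compatible choice, at the cost of slight misregistrations
  between iterations with different plane estimates. A `recompose_at_end`
  option exists for comparison, and the per-iteration plane trace is
  logged. An optional freeze stops re-estimating the plane after its
  relative change stays below 1e-6 for 5 iterations.

## Synthetic data

The simulator emulates a bench acquisition over a planar target: 368×378 px
frames, focal length 300 px, a fronto-parallel plane 50 mm away, a circular
xy-translation trajectory (radius 40 mm, ~50 frames per lap — adjacent
footprints overlap by >80 %) or a handheld constant-velocity + AR(1)-jitter
trajectory; tracker noise `ν × (1°, 1 mm)` per axis; correspondences drawn
uniformly in the pair's overlap with `σ_v` pixel noise; optional black-frame
dropout; and an optional rendering path that cuts frames from a seeded
procedural vessel-like texture (used by the feature-matching tests).
Everything is deterministic given the seed.

What it does **not** emulate: real fetoscopic image degradation (specular
reflections, amniotic fluid particles, low texture), outlier matches
(matching noise is inlier-Gaussian; in the real pipeline RANSAC removes
outliers upstream), correlated landmark errors, non-planarity, lens
distortion, or rolling shutter. Passing tests therefore demonstrate the
estimator's correctness under its own generative assumptions, not clinical
robustness.

## Problem sizes used by tests and the acceptance script

Exact recovery: 30 frames. Drift comparison: 150 frames (~3 laps), σ_v =
1 px, ν = 1; drift is declared via an OLS slope on (frame, e_j) at α = 0.01
and via the bounded-error check max(e_j, last third) ≤ 2·max(e_j, first
third). Batch-vs-sequential equivalence: 20 frames. Noise sweep: 17 frames
across ν ∈ {0.125, 0.25, 0.5, 1, 2, 3, 4} (seven values; fresh tracker
noise per cell, shared geometry). Dropout: 62 frames with frames
{7, 11, 12, 23, 24, 37, 38, 42, 43, 45, 51, 54} blacked out. Error metric:
`e_j` over a 100×100 uniform grid including the frame corners; `e_M` is the
plain mean over frames.

## Known limitations

* **First-window depth noise and fixed-camera lock-in.** With W = 5 frames
  (~20 mm baseline) and ν = 1 noise, the window's plane-depth estimate has
  ~5–10 % standard error; because previously estimated cameras are fixed,
  an unlucky first window contaminates subsequent iterations and recovery
  through anchors is slow. Over long sequences the estimate converges
  toward the batch value, but short sequences (e.g. 17 frames) can retain a
  several-percent depth error, and the resulting mosaic error then varies
  substantially between seeds. Re-weighting fixed cameras by their
  uncertainty would soften this and is deliberately out of scope.
* **Absolute accuracy scales with tracker noise.** The tracker term is the
  only source of absolute (mosaic-frame) information, so the common-mode
  component of the fusion error necessarily grows roughly like ν/√N; the
  fusion suppresses jitter relative to the tracker-only composition but is
  not ν-invariant.
* Revisited regions are only weakly constrained (overlap-predicted pairs
  against fixed anchors); there is no explicit loop-closure optimization.
* No robust kernels inside the optimizer; outliers must be removed
  upstream. Covariances are diagonal throughout.
* Linear (feathered) blending only; multiband blending is an extension
  point.
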