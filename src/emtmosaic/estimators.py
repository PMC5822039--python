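"""Scikit-learn-style estimators wrapping the mosaicking solvers.

Each estimator consumes a sequence object (duck-typed: ``n_frames``,
``intrinsics``, ``frame_size``, ``correspondences`` and, where needed,
``emt``) such as :class:`~emtmosaic.synthetic.SyntheticSequence` or
:class:`~emtmosaic.io.SequenceData`, and exposes fitted attributes with a
trailing underscore.  ``get_params`` / ``set_params`` come from
``sklearn.base.BaseEstimator``, so the estimators compose with scikit-learn
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .fusion import (
    EMTNoiseModel,
    MotionModel,
    ProblemState,
    SolveOptions,
    VisualNoiseModel,
    pairvis_chain,
    solve_bundle,
)
from .geometry import Plane, Pose, plane_homography, pose_compose, pose_inverse
from .lba import WindowConfig, run_sequential

__all__ = [
    "PairwiseChainMosaicker",
    "BundleAdjustmentMosaicker",
    "SlidingWindowMosaicker",
]

_DEFAULT_PLANE_DISTANCE_MM = 100.0  # nominal working-distance guess for the plane init


def _default_plane() -> Plane:
    return Plane.from_normal_distance([0, 0, 1], _DEFAULT_PLANE_DISTANCE_MM)


class PairwiseChainMosaicker(BaseEstimator):
    """The drifting vision-only baseline: chained pairwise DLT homographies.

    Fitted attributes: ``homographies_`` (mosaic-to-image, one per frame,
    ``H_0 = I``) and ``n_frames_``.
    """

    def __init__(self, refine: bool = True):
        self.refine = refine

    def fit(self, sequence, y=None):
        self.homographies_ = pairvis_chain(sequence.correspondences, sequence.n_frames)
        self.n_frames_ = sequence.n_frames
        return self


class BundleAdjustmentMosaicker(BaseEstimator):
    """Batch joint estimation of all poses and the plane.

    With ``use_emt=True`` this is bundle adjustment augmented with the
    tracker term (and optionally the constant-velocity prior); the tracker
    measurements also initialize the poses and fully constrain the gauge.
    With ``use_emt=False`` it is classical (visual-only) bundle adjustment in
    the minimal pose-plus-plane parametrization: pose 0 is clamped to the
    identity and the plane depth to its initial value (monocular scale
    ambiguity).

    Fitted attributes: ``poses_``, ``plane_``, ``homographies_``, ``report_``.
    """

    def __init__(self, use_emt: bool = True, use_motion_prior: bool = True,
                 sigma_v: float = 1.0, normalization: str = "per-pair-count",
                 sigma_emt_rot_deg: float = 1.0, sigma_emt_trans_mm: float = 1.0,
                 sigma_p_rot_deg: float = 0.5, sigma_p_trans_mm: float = 1.0,
                 plane_init: Plane | None = None, max_iter: int = 100,
                 tol: float = 1e-12):
        self.use_emt = use_emt
        self.use_motion_prior = use_motion_prior
        self.sigma_v = sigma_v
        self.normalization = normalization
        self.sigma_emt_rot_deg = sigma_emt_rot_deg
        self.sigma_emt_trans_mm = sigma_emt_trans_mm
        self.sigma_p_rot_deg = sigma_p_rot_deg
        self.sigma_p_trans_mm = sigma_p_trans_mm
        self.plane_init = plane_init
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, sequence, y=None):
        N = sequence.n_frames
        K = sequence.intrinsics
        emt = getattr(sequence, "emt", None)
        if self.use_emt and (emt is None or len(emt) != N):
            raise ValueError("use_emt=True requires one EMT measurement per frame")
        plane0 = (self.plane_init or _default_plane()).copy()

        if emt is not None:
            init_poses = [z.copy() for z in emt]
        else:
            init_poses = [Pose.identity() for _ in range(N)]
        if not self.use_emt:
            # express the initialization relative to frame 0 so the gauge
            # clamp (pose 0 = identity) is consistent with it
            z0_inv = pose_inverse(init_poses[0])
            init_poses = [pose_compose(p, z0_inv) for p in init_poses]

        free_mask = np.ones(N, dtype=bool)
        if not self.use_emt:
            free_mask[0] = False
        state = ProblemState(init_poses, plane0, free_mask, True)
        options = SolveOptions(
            intrinsics=K, max_iter=self.max_iter,
            ftol=self.tol, xtol=self.tol, gtol=self.tol,
            plane_mode="full" if self.use_emt else "direction",
            use_motion_prior=self.use_motion_prior,
        )
        motion_model = (
            MotionModel.from_sigmas(self.sigma_p_rot_deg, self.sigma_p_trans_mm)
            if self.use_motion_prior else None
        )
        new_state, report = solve_bundle(
            state, sequence.correspondences,
            Z=emt if self.use_emt else None,
            visual_model=VisualNoiseModel(self.sigma_v, self.normalization),
            emt_model=EMTNoiseModel.from_sigmas(
                self.sigma_emt_rot_deg, self.sigma_emt_trans_mm),
            motion_model=motion_model,
            options=options,
        )
        self.poses_ = new_state.poses
        self.plane_ = new_state.plane
        self.homographies_ = [plane_homography(p, self.plane_, K) for p in self.poses_]
        self.report_ = report
        self.n_frames_ = N
        return self


class SlidingWindowMosaicker(BaseEstimator):
    """Sequential windowed fusion of visual and tracker data (drift-free).

    Parameters mirror the window configuration (``window = chi_e + chi_g``
    frames per solve, ``n_estimate = chi_e`` newly estimated per iteration,
    K-means anchor selection with ``n_anchor_clusters`` clusters of
    ``anchor_run_length`` consecutive frames) and the three noise models.

    Fitted attributes: ``poses_``, ``plane_``, ``plane_trace_``,
    ``homographies_``, ``reports_``, ``window_log_``.
    """

    def __init__(self, window: int = 5, n_estimate: int = 3,
                 n_anchor_clusters: int = 3, anchor_run_length: int = 5,
                 sigma_v: float = 1.0, normalization: str = "per-pair-count",
                 sigma_emt_rot_deg: float = 1.0, sigma_emt_trans_mm: float = 1.0,
                 sigma_p_rot_deg: float = 0.5, sigma_p_trans_mm: float = 1.0,
                 plane_init: Plane | None = None, freeze_plane: bool = False,
                 recompose_at_end: bool = False, seed: int = 0,
                 max_iter: int = 100, tol: float = 1e-12,
                 anchor_overlap_radius: float | None = None):
        self.window = window
        self.n_estimate = n_estimate
        self.n_anchor_clusters = n_anchor_clusters
        self.anchor_run_length = anchor_run_length
        self.sigma_v = sigma_v
        self.normalization = normalization
        self.sigma_emt_rot_deg = sigma_emt_rot_deg
        self.sigma_emt_trans_mm = sigma_emt_trans_mm
        self.sigma_p_rot_deg = sigma_p_rot_deg
        self.sigma_p_trans_mm = sigma_p_trans_mm
        self.plane_init = plane_init
        self.freeze_plane = freeze_plane
        self.recompose_at_end = recompose_at_end
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.anchor_overlap_radius = anchor_overlap_radius

    def fit(self, sequence, y=None, provider=None):
        config = WindowConfig(
            W=self.window, chi_e=self.n_estimate,
            K_clusters=self.n_anchor_clusters, subset_len=self.anchor_run_length,
            seed=self.seed, anchor_overlap_radius=self.anchor_overlap_radius,
            freeze_plane=self.freeze_plane, recompose_at_end=self.recompose_at_end,
        )
        result = run_sequential(
            sequence, config,
            visual_model=VisualNoiseModel(self.sigma_v, self.normalization),
            emt_model=EMTNoiseModel.from_sigmas(
                self.sigma_emt_rot_deg, self.sigma_emt_trans_mm),
            motion_model=MotionModel.from_sigmas(
                self.sigma_p_rot_deg, self.sigma_p_trans_mm),
            plane_init=self.plane_init,
            provider=provider,
            solve_options=SolveOptions(
                max_iter=self.max_iter, ftol=self.tol, xtol=self.tol, gtol=self.tol,
            ),
        )
        self.poses_ = result.poses
        self.plane_ = result.plane
        self.plane_trace_ = result.plane_trace
        self.homographies_ = result.homographies
        self.reports_ = result.reports
        self.window_log_ = result.window_log
        self.result_ = result
        return self
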