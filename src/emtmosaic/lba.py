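"""Sequential estimation by local bundle adjustment over a sliding window.

Each iteration estimates the ``chi_e`` newest camera poses (and the plane)
while the previous ``chi_g = W - chi_e`` cameras of the window enter the
residuals as fixed constants; cameras estimated earlier leave the window and
are never touched again.  Because a short temporal window gives little
baseline for the plane depth, every iteration additionally selects spatially
distributed *anchor* cameras among the already-fixed ones — K-means clusters
of the projected image-footprint centroids, with one consecutive run of
frames drawn per cluster — whose correspondences contribute visual residuals
(constraining the plane only, since the anchor poses are fixed).

Frames without visual content (e.g. black frames) are still estimated from
their tracker measurement and the constant-velocity prior, so the pipeline
never aborts on missing visual data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .correspondences import (
    CorrespondenceCollection,
    MatchParams,
    detect_and_match,
    enumerate_window_pairs,
)
from .errors import DegenerateGeometryError
from .fusion import (
    EMTNoiseModel,
    MotionModel,
    ProblemState,
    SolveOptions,
    VisualNoiseModel,
    solve_bundle,
)
from .geometry import Homography, Intrinsics, Plane, Pose, apply_homography, plane_homography

__all__ = [
    "WindowConfig",
    "WindowState",
    "AnchorSelection",
    "LBAResult",
    "project_footprint_centroid",
    "select_anchors",
    "advance_window",
    "run_sequential",
    "compose_mosaic_homographies",
    "CollectionProvider",
    "MatcherProvider",
]


@dataclass
class WindowConfig:
    """Sliding-window sizes: W = chi_e + chi_g, plus anchor selection knobs."""

    W: int = 5
    chi_e: int = 3
    K_clusters: int = 3
    subset_len: int = 5
    seed: int = 0
    anchor_overlap_radius: float | None = None
    freeze_plane: bool = False
    freeze_tol: float = 1e-6
    freeze_patience: int = 5
    recompose_at_end: bool = False

    def __post_init__(self):
        if not (1 <= self.chi_e <= self.W):
            raise ValueError("require 1 <= chi_e <= W")
        if self.K_clusters < 1 or self.subset_len < 1:
            raise ValueError("K_clusters and subset_len must be >= 1")


@dataclass
class WindowState:
    """Partition of processed frames into estimate / fixed-in-window / outside."""

    estimate_ids: list
    fixed_in_window_ids: list
    outside_ids: list

    @property
    def chi_g(self) -> int:
        return len(self.fixed_in_window_ids)

    @property
    def emt_subset(self) -> list:
        return list(self.estimate_ids)

    def all_processed(self) -> list:
        return sorted(self.outside_ids + self.fixed_in_window_ids + self.estimate_ids)


@dataclass
class AnchorSelection:
    cluster_centroids: np.ndarray
    runs: list  # list of lists of consecutive frame ids
    anchor_ids: list = field(init=False)

    def __post_init__(self):
        self.anchor_ids = sorted({i for run in self.runs for i in run})


@dataclass
class LBAResult:
    poses: list
    plane: Plane
    plane_trace: list
    homographies: list
    reports: list
    window_log: list


# ---------------------------------------------------------------------------
# footprints and anchors
# ---------------------------------------------------------------------------


def project_footprint_centroid(pose: Pose, plane: Plane, K: Intrinsics,
                               frame_size) -> np.ndarray:
    """Mean of the four frame corners mapped into mosaic space through H^{-1}."""
    w, h = frame_size
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    H = plane_homography(pose, plane, K)
    return apply_homography(np.linalg.inv(H.H), corners).mean(axis=0)


def _consecutive_runs(ids):
    runs, cur = [], []
    for i in ids:
        if cur and i != cur[-1] + 1:
            runs.append(cur)
            cur = []
        cur.append(i)
    if cur:
        runs.append(cur)
    return runs


def select_anchors(fixed_ids, poses, plane: Plane, K: Intrinsics, frame_size,
                   config: WindowConfig, rng: np.random.Generator) -> AnchorSelection:
    """K-means over footprint centroids; one seeded-random consecutive run per cluster.

    With fewer fixed cameras than clusters every fixed camera is selected.
    Runs longer than the cluster's consecutive membership are clipped to it.
    """
    fixed_ids = sorted(int(i) for i in fixed_ids)
    if not fixed_ids:
        raise ValueError("need at least one fixed camera to select anchors")
    cents = np.array([
        project_footprint_centroid(poses[i], plane, K, frame_size) for i in fixed_ids
    ])
    if len(fixed_ids) <= config.K_clusters:
        return AnchorSelection(cents, _consecutive_runs(fixed_ids))
    km = KMeans(
        n_clusters=config.K_clusters, n_init=4,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(cents)
    runs = []
    for c in range(config.K_clusters):
        members = [fixed_ids[j] for j in np.flatnonzero(km.labels_ == c)]
        if not members:
            continue
        cand = _consecutive_runs(members)
        run = cand[rng.integers(len(cand))]
        if len(run) > config.subset_len:
            start = rng.integers(len(run) - config.subset_len + 1)
            run = run[start:start + config.subset_len]
        runs.append(run)
    return AnchorSelection(km.cluster_centers_, runs)


def advance_window(state: WindowState, config: WindowConfig, n_frames: int) -> WindowState:
    """Move estimated cameras to fixed, overflow to outside, take the next chi_e.

    After every advance the three sets partition the processed frames and
    ``|X^e| + |X^g| = W`` (clipped at the sequence boundaries).
    """
    processed = state.all_processed()
    next_start = (processed[-1] + 1) if processed else 0
    estimate = list(range(next_start, min(next_start + config.chi_e, n_frames)))
    chi_g = config.W - len(estimate)
    fixed = processed[-chi_g:] if chi_g > 0 else []
    outside = processed[:len(processed) - len(fixed)]
    return WindowState(estimate, fixed, outside)


# ---------------------------------------------------------------------------
# correspondence providers
# ---------------------------------------------------------------------------


class CollectionProvider:
    """Serve correspondences for requested pairs from a precomputed collection."""

    def __init__(self, collection: CorrespondenceCollection):
        self.collection = collection

    def get(self, m: int, l: int):
        return self.collection.get(m, l)


class MatcherProvider:
    """Run the feature frontend on demand, with caching."""

    def __init__(self, frames, params: MatchParams | None = None):
        self.frames = frames
        self.params = params or MatchParams()
        self._cache = {}

    def get(self, m: int, l: int):
        key = (m, l)
        if key not in self._cache:
            self._cache[key] = detect_and_match(
                self.frames[m], self.frames[l], self.params, pair=key
            )
        return self._cache[key]


# ---------------------------------------------------------------------------
# the sequencer
# ---------------------------------------------------------------------------


def compose_mosaic_homographies(poses, plane: Plane, K: Intrinsics) -> list:
    """``H_j`` for every pose from a single plane estimate."""
    return [plane_homography(p, plane, K) for p in poses]


def run_sequential(sequence, config: WindowConfig | None = None,
                   visual_model: VisualNoiseModel | None = None,
                   emt_model: EMTNoiseModel | None = None,
                   motion_model: MotionModel | None = None,
                   plane_init: Plane | None = None,
                   provider=None,
                   solve_options: SolveOptions | None = None) -> LBAResult:
    """Sequential windowed fusion over a full sequence.

    The first window is solved as one batch (the tracker term fixes the
    gauge, so no pose needs clamping); afterwards the window advances by
    ``chi_e`` frames per iteration.  With ``W = chi_e = N`` the first and
    only iteration is exactly the batch visual+EMT problem.
    Homographies of newly estimated frames are composed with
    the plane of the iteration that fixed them and are not recomposed when
    the plane later moves (set ``config.recompose_at_end`` to compare).
    """
    config = config or WindowConfig()
    visual_model = visual_model or VisualNoiseModel()
    emt_model = emt_model or EMTNoiseModel()
    motion_model = motion_model or MotionModel()
    K = sequence.intrinsics
    N = sequence.n_frames
    emt = sequence.emt
    if emt is None or len(emt) != N:
        raise ValueError("sequential estimation requires one EMT measurement per frame")
    if provider is None:
        provider = CollectionProvider(sequence.correspondences)
    plane_cur = (plane_init or Plane.from_normal_distance([0, 0, 1], 100.0)).copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))

    base_opts = solve_options or SolveOptions()
    poses_cur = [z.copy() for z in emt]
    homographies = [None] * N
    plane_trace, reports, window_log = [], [], []
    frozen = False
    small_changes = 0

    win = WindowState(list(range(min(config.W, N))), [], [])
    while win.estimate_ids:
        est = win.estimate_ids
        window_ids = sorted(win.fixed_in_window_ids + est)

        # --- gather correspondences: window pairs + anchors
        anchor_runs = []
        pairs = [(a, b) for a, b in zip(window_ids[:-1], window_ids[1:])]
        fixed_all = sorted(win.outside_ids + win.fixed_in_window_ids)
        if fixed_all:
            sel = select_anchors(fixed_all, poses_cur, plane_cur, K,
                                 sequence.frame_size, config, rng)
            anchor_runs = sel.runs
            for run in sel.runs:
                pairs += [(a, b) for a, b in zip(run[:-1], run[1:])]
            pairs = list(dict.fromkeys(
                pairs + enumerate_window_pairs(
                    window_ids, sel.anchor_ids, poses_cur, plane_cur, K,
                    sequence.frame_size, config.anchor_overlap_radius,
                )
            ))
        corrs = CorrespondenceCollection()
        for (m, l) in pairs:
            s = provider.get(m, l)
            if s is not None and len(s) > 0 and (m, l) not in corrs:
                corrs.add(s)

        # --- build the window problem
        free_mask = np.zeros(N, dtype=bool)
        free_mask[est] = True
        emt_ids = list(est)
        has_visual = len(corrs) > 0
        free_plane = has_visual and not frozen
        state = ProblemState(
            [p.copy() for p in poses_cur], plane_cur.copy(),
            free_mask, free_plane,
        )
        opts = SolveOptions(
            intrinsics=K, max_iter=base_opts.max_iter,
            ftol=base_opts.ftol, xtol=base_opts.xtol, gtol=base_opts.gtol,
            plane_mode="full",
            emt_ids=emt_ids, prior_ks=[k for k in est if k >= 2],
        )
        if not free_mask.any() and not free_plane:
            # nothing to estimate (single clamped frame, no visual): keep init
            new_state, report = state, None
        else:
            try:
                new_state, report = solve_bundle(
                    state, corrs, [emt[i] for i in emt_ids],
                    visual_model, emt_model, motion_model, opts,
                )
            except (ValueError, DegenerateGeometryError):
                # fall back to the tracker measurements for this window
                new_state, report = state, None
        for i in est:
            poses_cur[i] = new_state.poses[i]
        prev_plane = plane_cur
        if free_plane:
            plane_cur = new_state.plane

        # --- freeze-plane bookkeeping
        if config.freeze_plane and not frozen and free_plane:
            rel = np.linalg.norm(plane_cur.pi - prev_plane.pi) / np.linalg.norm(prev_plane.pi)
            small_changes = small_changes + 1 if rel < config.freeze_tol else 0
            if small_changes >= config.freeze_patience:
                frozen = True

        # --- compose this iteration's homographies with the current plane
        for i in est:
            homographies[i] = plane_homography(poses_cur[i], plane_cur, K)
        plane_trace.append(plane_cur.copy())
        reports.append(report)
        window_log.append({
            "estimate_ids": list(est),
            "fixed_in_window_ids": list(win.fixed_in_window_ids),
            "anchor_runs": [list(r) for r in anchor_runs],
            "n_pairs": len(corrs),
            "cost_terms": None if report is None else report.cost_terms,
            "plane": plane_cur.pi.tolist(),
            "fallback": report is None,
        })
        win = advance_window(win, config, N)

    if config.recompose_at_end:
        homographies = compose_mosaic_homographies(poses_cur, plane_cur, K)
    return LBAResult(
        poses=poses_cur, plane=plane_cur, plane_trace=plane_trace,
        homographies=homographies, reports=reports, window_log=window_log,
    )
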