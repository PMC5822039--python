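"""Synthetic planar-scene sequences with tracked-pose and correspondence noise.

This module emulates the bench-top synthetic study conditions used throughout
the test suite: a camera moving over a planar texture along a known
trajectory, per-frame 6-DOF pose measurements corrupted by Gaussian noise
whose standard deviation is a multiplier ``nu`` times a base of 1 degree and
1 mm per axis, point correspondences drawn from the ground-truth homographies
with isotropic pixel noise ``sigma_v``, and optional black-frame dropout.

Because the probabilistic model downstream consumes correspondences rather
than pixels, the simulator can emit correspondences directly (the fast path
used by the solver tests); rendering actual frames from the texture is an
optional slower path exercised by the matching frontend tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, warp

from .correspondences import CorrespondenceCollection, CorrespondenceSet
from .errors import OutOfBoundsError
from .geometry import (
    Homography,
    Intrinsics,
    Plane,
    Pose,
    apply_homography,
    plane_homography,
)

__all__ = [
    "SceneConfig",
    "EMTNoiseConfig",
    "GroundTruth",
    "SyntheticSequence",
    "SyntheticCorrespondenceProvider",
    "procedural_texture",
    "make_trajectory",
    "render_frames",
    "simulate_emt",
    "synthesize_correspondences",
    "blank_frames",
    "make_sequence",
]


def default_intrinsics(frame_size=(368, 378), focal=300.0) -> Intrinsics:
    w, h = frame_size
    return Intrinsics(fx=focal, fy=focal, cx=(w - 1) / 2.0, cy=(h - 1) / 2.0)


@dataclass
class SceneConfig:
    """Geometry and trajectory of a synthetic sequence.

    The defaults describe the bench configuration used across the package's
    experiments: 368x378 frames (the synthetic dataset's frame size), a
    fronto-parallel plane 50 mm in front of the reference camera, a focal
    length of 300 px, and a circular xy-translation trajectory of four laps
    with a 40 mm radius — small enough that adjacent frames overlap by well
    over half their width.
    """

    frame_size: tuple[int, int] = (368, 378)  # (w, h) px
    kind: str = "circular"  # {"circular", "handheld"}
    n_frames: int = 200
    laps: float = 4.0
    radius_mm: float = 40.0
    plane: Plane = field(default_factory=lambda: Plane.from_normal_distance([0, 0, 1], 50.0))
    intrinsics: Intrinsics | None = None
    seed: int = 0
    # handheld-only parameters: constant-velocity base + AR(1) jitter
    vel_rot_deg: tuple = (0.05, 0.05, 0.1)  # deg / frame
    vel_trans_mm: tuple = (1.2, 0.6, 0.05)  # mm / frame
    jitter_rot_deg: float = 0.05
    jitter_trans_mm: float = 0.25
    jitter_ar1: float = 0.8

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.intrinsics is None:
            self.intrinsics = default_intrinsics(self.frame_size)


@dataclass
class EMTNoiseConfig:
    """Tracker noise: per-axis std = ``nu`` x (base_sigma_rot deg, base_sigma_trans mm)."""

    nu: float = 1.0
    base_sigma_rot: float = 1.0  # degrees
    base_sigma_trans: float = 1.0  # mm
    seed: int = 0

    def __post_init__(self):
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if not (self.base_sigma_rot > 0 and self.base_sigma_trans > 0):
            raise ValueError("base sigmas must be positive")

    @property
    def sigma_rot_rad(self) -> float:
        return np.radians(self.nu * self.base_sigma_rot)

    @property
    def sigma_trans_mm(self) -> float:
        return self.nu * self.base_sigma_trans


@dataclass
class GroundTruth:
    poses: list
    plane: Plane
    gt_homographies: list


@dataclass
class SyntheticSequence:
    """Everything a solver needs: measurements, correspondences, and the truth."""

    emt: list
    correspondences: CorrespondenceCollection
    ground_truth: GroundTruth
    intrinsics: Intrinsics
    frame_size: tuple[int, int]
    frames: list | None = None
    blank_indices: set = field(default_factory=set)

    @property
    def n_frames(self) -> int:
        return len(self.ground_truth.poses)


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------


def procedural_texture(shape=(1024, 1024), seed: int = 0) -> np.ndarray:
    """Seeded vessel-like RGB texture (filtered noise + dark meandering curves).

    Provides enough unstructured detail for SIFT and for photometric oracles
    without requiring any image download.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), 6)
    detail = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.5)
    field_ = base / (np.abs(base).max() + 1e-12) + 0.6 * detail / (np.abs(detail).max() + 1e-12)
    field_ = (field_ - field_.min()) / (np.ptp(field_) + 1e-12)

    vessels = np.zeros((h, w))
    n_curves = max(6, (h * w) // 80000)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_curves):
        pos = rng.uniform([0, 0], [h, w])
        ang = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(2.5, 6.0)
        for _ in range(rng.integers(150, 300)):
            ang += rng.normal(0, 0.25)
            pos = pos + 4.0 * np.array([np.sin(ang), np.cos(ang)])
            pos = np.clip(pos, 0, [h - 1, w - 1])
            r0, c0 = int(pos[0]), int(pos[1])
            rad = int(np.ceil(width)) + 1
            rs = slice(max(0, r0 - rad), min(h, r0 + rad + 1))
            cs = slice(max(0, c0 - rad), min(w, c0 + rad + 1))
            d2 = (yy[rs, cs] - pos[0]) ** 2 + (xx[rs, cs] - pos[1]) ** 2
            vessels[rs, cs] = np.maximum(vessels[rs, cs], np.exp(-d2 / (2 * width**2)))

    red = 140 + 90 * field_ - 80 * vessels
    green = 60 + 60 * field_ - 45 * vessels
    blue = 55 + 45 * field_ - 40 * vessels
    tex = np.stack([red, green, blue], axis=-1)
    return np.clip(tex, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# trajectory and ground truth
# ---------------------------------------------------------------------------


def make_trajectory(config: SceneConfig) -> list:
    """Ground-truth poses for the configured trajectory kind.

    ``circular``: pure xy-translation on a circle of the given radius in a
    plane parallel to the scene, identity rotation, starting at the origin.
    ``handheld``: constant-velocity rigid motion (T_k = V T_{k-1}) plus a
    seeded AR(1) perturbation on all six pose components.
    """
    if config.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    n = config.n_frames
    if config.kind == "circular":
        theta = 2 * np.pi * config.laps * np.arange(n) / n
        poses = [
            Pose(np.zeros(3),
                 config.radius_mm * np.array([np.cos(th) - 1.0, np.sin(th), 0.0]))
            for th in theta
        ]
        return poses
    if config.kind == "handheld":
        V = Pose(np.radians(config.vel_rot_deg), np.array(config.vel_trans_mm)).matrix()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        poses = []
        T = np.eye(4)
        s = np.zeros(6)
        sig = np.concatenate([
            np.full(3, np.radians(config.jitter_rot_deg)),
            np.full(3, config.jitter_trans_mm),
        ])
        for _ in range(n):
            base = Pose.from_matrix(T)
            s = config.jitter_ar1 * s + rng.normal(0.0, 1.0, 6) * sig
            poses.append(Pose.from_vector(base.as_vector() + s))
            T = V @ T
        return poses
    raise ValueError(f"unknown trajectory kind {config.kind!r}")


def ground_truth_from_config(config: SceneConfig) -> GroundTruth:
    poses = make_trajectory(config)
    Hs = [plane_homography(p, config.plane, config.intrinsics) for p in poses]
    return GroundTruth(poses=poses, plane=config.plane, gt_homographies=Hs)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


def simulate_emt(poses, noise: EMTNoiseConfig) -> list:
    """Per-frame tracker measurements ``z_k = x_k + eps`` with diagonal Gaussian eps.

    Rotation noise is additive on the rotation-vector components; seeded and
    reproducible.  With ``nu = 0`` the measurements equal the true poses.
    """
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 11]))
    out = []
    for p in poses:
        eps_r = rng.normal(0.0, 1.0, 3) * noise.sigma_rot_rad
        eps_t = rng.normal(0.0, 1.0, 3) * noise.sigma_trans_mm
        out.append(Pose(p.r + eps_r, p.t + eps_t))
    return out


def synthesize_correspondences(ground_truth: GroundTruth, K: Intrinsics, pairs,
                               frame_size=(368, 378), n_points: int = 50,
                               sigma_v: float = 1.0, seed: int = 0,
                               ) -> CorrespondenceCollection:
    """Noisy correspondences drawn from the ground-truth pairwise homographies.

    For each pair ``(m, l)``, points are sampled uniformly in frame ``m``,
    kept when their ground-truth image lies inside frame ``l``, and the
    partner point is that image plus isotropic N(0, sigma_v^2) pixel noise
    (resampled if the noisy point falls outside frame ``l``).  Pairs with no
    overlap are omitted.  Each pair draws from its own seeded stream, so the
    output is independent of pair enumeration order.
    """
    w, h = frame_size
    Hs = [H.H for H in ground_truth.gt_homographies]
    coll = CorrespondenceCollection()
    for (m, l) in pairs:
        H_lm = Hs[l] @ np.linalg.inv(Hs[m])
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(m), int(l)]))
        pts_a, pts_b = [], []
        attempts = 0
        while len(pts_a) < n_points and attempts < 200 * n_points:
            need = n_points - len(pts_a)
            attempts += need
            qa = rng.uniform([0, 0], [w - 1, h - 1], size=(need, 2))
            qb_true = apply_homography(H_lm, qa)
            inside = (
                (qb_true[:, 0] >= 0) & (qb_true[:, 0] <= w - 1)
                & (qb_true[:, 1] >= 0) & (qb_true[:, 1] <= h - 1)
            )
            qa, qb_true = qa[inside], qb_true[inside]
            if len(qa) == 0:
                continue
            qb = qb_true + rng.normal(0.0, 1.0, qa.shape) * sigma_v
            ok = (
                (qb[:, 0] >= 0) & (qb[:, 0] <= w - 1)
                & (qb[:, 1] >= 0) & (qb[:, 1] <= h - 1)
            )
            pts_a.extend(qa[ok])
            pts_b.extend(qb[ok])
        if len(pts_a) == 0:
            continue  # no overlap between this pair; omit it
        pts_a = np.array(pts_a[:n_points])
        pts_b = np.array(pts_b[:n_points])
        coll.add(CorrespondenceSet((m, l), pts_a, pts_b))
    return coll


class SyntheticCorrespondenceProvider:
    """Serve correspondences for *any* requested pair, synthesized on demand.

    Emulates a matcher that can register any overlapping pair (e.g. the
    revisit pairs the sequential estimator requests between the current
    window and spatial anchors), drawing each pair from its own seeded
    stream so results do not depend on request order.  Pairs touching
    blanked frames yield no match.
    """

    def __init__(self, sequence: "SyntheticSequence", n_points: int = 50,
                 sigma_v: float = 1.0, seed: int = 0):
        self.sequence = sequence
        self.n_points = n_points
        self.sigma_v = sigma_v
        self.seed = seed
        self._cache: dict = {}

    def get(self, m: int, l: int):
        key = (int(m), int(l))
        if key in self._cache:
            return self._cache[key]
        if key[0] in self.sequence.blank_indices or key[1] in self.sequence.blank_indices:
            result = None
        else:
            coll = synthesize_correspondences(
                self.sequence.ground_truth, self.sequence.intrinsics, [key],
                frame_size=self.sequence.frame_size, n_points=self.n_points,
                sigma_v=self.sigma_v, seed=self.seed,
            )
            result = coll.get(*key)
        self._cache[key] = result
        return result


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def mosaic_footprints(ground_truth: GroundTruth, frame_size) -> np.ndarray:
    """Stacked mosaic-space corner coordinates, one (4, 2) block per frame."""
    w, h = frame_size
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    return np.stack([
        apply_homography(np.linalg.inv(H.H), corners)
        for H in ground_truth.gt_homographies
    ])


def render_frames(texture: np.ndarray, ground_truth: GroundTruth, K: Intrinsics,
                  frame_size, offset=None, margin: float = 8.0) -> list:
    """Cut each frame out of a large planar texture through its homography.

    Frame ``k`` pixel ``q`` samples the texture (bilinearly) at
    ``H_k^{-1}(q) + offset``, i.e. the texture is the mosaic plane shifted by
    ``offset``.  When ``offset`` is None it is chosen so all footprints fit;
    a footprint leaving the texture raises :class:`OutOfBoundsError` naming
    the offending frame.
    """
    texture = np.asarray(texture)
    th, tw = texture.shape[:2]
    w, h = frame_size
    feet = mosaic_footprints(ground_truth, frame_size)
    if offset is None:
        lo = feet.reshape(-1, 2).min(axis=0)
        offset = -lo + margin
    offset = np.asarray(offset, dtype=float)
    frames = []
    for k, H in enumerate(ground_truth.gt_homographies):
        corners_tex = feet[k] + offset
        if (corners_tex.min() < 0 or corners_tex[:, 0].max() > tw - 1
                or corners_tex[:, 1].max() > th - 1):
            raise OutOfBoundsError(f"frame {k} footprint leaves the texture")
        T = np.eye(3)
        T[:2, 2] = offset
        tform = ProjectiveTransform(matrix=T @ np.linalg.inv(H.H))
        img = warp(texture.astype(float), tform, output_shape=(h, w),
                   order=1, preserve_range=True)
        frames.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
    return frames


# ---------------------------------------------------------------------------
# dropout and assembly
# ---------------------------------------------------------------------------


def blank_frames(sequence: SyntheticSequence, indices) -> SyntheticSequence:
    """Replace the listed frames by black images and drop their correspondences.

    Tracker measurements are retained: the estimator can still place a frame
    with no visual content from its pose measurement and the motion prior.
    """
    indices = set(int(i) for i in indices)
    n = sequence.n_frames
    for i in indices:
        if not (0 <= i < n):
            raise ValueError(f"blank index {i} out of range for {n} frames")
    frames = None
    if sequence.frames is not None:
        frames = [
            np.zeros_like(f) if k in indices else f
            for k, f in enumerate(sequence.frames)
        ]
    return SyntheticSequence(
        emt=list(sequence.emt),
        correspondences=sequence.correspondences.without_frames(indices),
        ground_truth=sequence.ground_truth,
        intrinsics=sequence.intrinsics,
        frame_size=sequence.frame_size,
        frames=frames,
        blank_indices=set(sequence.blank_indices) | indices,
    )


def make_sequence(config: SceneConfig, emt_noise: EMTNoiseConfig | None = None,
                  sigma_v: float = 1.0, n_points: int = 50, pairs="adjacent",
                  render: bool = False, texture: np.ndarray | None = None,
                  ) -> SyntheticSequence:
    """One-stop generator: trajectory, truth, measurements, correspondences.

    ``pairs`` is either the string "adjacent" (all consecutive pairs — the
    sequential estimator's anchor runs are consecutive too, so this covers
    every pair it requests) or an explicit list of ``(m, l)`` tuples.
    """
    emt_noise = emt_noise or EMTNoiseConfig(seed=config.seed)
    gt = ground_truth_from_config(config)
    if pairs == "adjacent":
        pairs = [(k, k + 1) for k in range(config.n_frames - 1)]
    corrs = synthesize_correspondences(
        gt, config.intrinsics, pairs, frame_size=config.frame_size,
        n_points=n_points, sigma_v=sigma_v, seed=config.seed,
    )
    emt = simulate_emt(gt.poses, emt_noise)
    frames = None
    if render:
        if texture is None:
            feet = mosaic_footprints(gt, config.frame_size).reshape(-1, 2)
            span = feet.max(axis=0) - feet.min(axis=0) + 2 * 8.0
            shape = (int(np.ceil(span[1])) + 1, int(np.ceil(span[0])) + 1)
            texture = procedural_texture(shape, seed=config.seed)
        frames = render_frames(texture, gt, config.intrinsics, config.frame_size)
    return SyntheticSequence(
        emt=emt, correspondences=corrs, ground_truth=gt,
        intrinsics=config.intrinsics, frame_size=config.frame_size, frames=frames,
    )
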