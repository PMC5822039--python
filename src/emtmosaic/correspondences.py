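"""Pairwise point correspondences: containers and a feature-based frontend.

The matching frontend is deliberately standard (SIFT descriptors, Lowe ratio
test, RANSAC with a projective model) and pluggable; the probabilistic model
downstream only consumes :class:`CorrespondenceSet` objects, however obtained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform

from .geometry import Homography, Intrinsics, Plane, Pose, apply_homography

__all__ = [
    "CorrespondenceSet",
    "CorrespondenceCollection",
    "MatchParams",
    "detect_and_match",
    "enumerate_window_pairs",
]


@dataclass
class CorrespondenceSet:
    """Matched points between an ordered frame pair ``(m -> l)`` with ``m < l``.

    ``points_a`` live in frame ``m`` (the source image A), ``points_b`` in
    frame ``l`` (the target image B); row i of each array is one match.
    """

    pair: tuple[int, int]
    points_a: np.ndarray
    points_b: np.ndarray

    def __post_init__(self):
        self.pair = (int(self.pair[0]), int(self.pair[1]))
        self.points_a = np.asarray(self.points_a, dtype=float).reshape(-1, 2)
        self.points_b = np.asarray(self.points_b, dtype=float).reshape(-1, 2)
        if len(self.points_a) != len(self.points_b):
            raise ValueError("points_a and points_b must have equal length")

    def __len__(self) -> int:
        return len(self.points_a)


class CorrespondenceCollection:
    """All correspondence sets of a sequence, keyed by ordered pair ``(m, l)``."""

    def __init__(self, sets=()):
        self._sets: dict[tuple[int, int], CorrespondenceSet] = {}
        for s in sets:
            self.add(s)

    def add(self, s: CorrespondenceSet) -> None:
        if s.pair in self._sets:
            raise ValueError(f"duplicate correspondence set for pair {s.pair}")
        self._sets[s.pair] = s

    def get(self, m: int, l: int):
        return self._sets.get((m, l))

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self._sets)

    def sets(self):
        return [self._sets[p] for p in self.pairs]

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self._sets

    def total_points(self) -> int:
        return sum(len(s) for s in self._sets.values())

    def subset(self, pairs) -> "CorrespondenceCollection":
        out = CorrespondenceCollection()
        for p in pairs:
            s = self._sets.get(tuple(p))
            if s is not None:
                out.add(s)
        return out

    def without_frames(self, frames) -> "CorrespondenceCollection":
        """Drop every set that touches any of the given frame indices."""
        frames = set(int(f) for f in frames)
        return CorrespondenceCollection(
            s for s in self._sets.values()
            if s.pair[0] not in frames and s.pair[1] not in frames
        )


# ---------------------------------------------------------------------------
# feature-based matching
# ---------------------------------------------------------------------------


@dataclass
class MatchParams:
    """Knobs of the standard SIFT + ratio test + RANSAC pipeline."""

    ratio: float = 0.8
    ransac_threshold: float = 3.0  # px reprojection
    ransac_max_trials: int = 1000
    min_inliers: int = 8
    seed: int = 0


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        return rgb2gray(img)
    return img.astype(float) / (255.0 if img.dtype == np.uint8 else 1.0)


def detect_and_match(img_a, img_b, params: MatchParams | None = None,
                     pair: tuple[int, int] = (0, 1)):
    """SIFT + Lowe-ratio matching + projective RANSAC between two images.

    Returns a :class:`CorrespondenceSet` of RANSAC inliers, or ``None``
    (no-match) when fewer than ``params.min_inliers`` survive — the signal the
    sequential estimator uses to treat a frame as visually missing (e.g. an
    all-black frame has no detectable features at all).
    """
    params = params or MatchParams()
    ga, gb = _as_gray(img_a), _as_gray(img_b)
    if ga.shape[-1] == 0 or gb.shape[-1] == 0:
        raise OSError("unreadable/empty image")

    det_a, det_b = SIFT(), SIFT()
    try:
        det_a.detect_and_extract(ga)
        det_b.detect_and_extract(gb)
    except RuntimeError:
        return None  # no features found (e.g. constant image)
    if len(det_a.keypoints) < params.min_inliers or len(det_b.keypoints) < params.min_inliers:
        return None

    matches = match_descriptors(
        det_a.descriptors, det_b.descriptors,
        cross_check=True, max_ratio=params.ratio,
    )
    if len(matches) < max(4, params.min_inliers):
        return None

    # skimage keypoints are (row, col); convert to (x, y)
    pts_a = det_a.keypoints[matches[:, 0]][:, ::-1].astype(float)
    pts_b = det_b.keypoints[matches[:, 1]][:, ::-1].astype(float)
    try:
        _, inliers = ransac(
            (pts_a, pts_b), ProjectiveTransform,
            min_samples=4, residual_threshold=params.ransac_threshold,
            max_trials=params.ransac_max_trials, rng=params.seed,
        )
    except ValueError:
        return None
    if inliers is None or inliers.sum() < params.min_inliers:
        return None
    return CorrespondenceSet(pair, pts_a[inliers], pts_b[inliers])


# ---------------------------------------------------------------------------
# pair enumeration for windowed estimation
# ---------------------------------------------------------------------------


def enumerate_window_pairs(window_ids, anchor_ids=(), poses=None, plane=None,
                           K=None, frame_size=None, overlap_radius=None):
    """Pairs to match for one windowed solve.

    Always returns all temporally adjacent pairs within ``window_ids``.  When
    anchors and current geometric estimates are supplied, also returns
    (anchor, window) pairs whose projected footprint centroids lie within
    ``overlap_radius`` mosaic pixels of each other (overlap predicted from the
    current estimates).  Pairs are ordered ``(m, l)`` with ``m < l``.
    """
    window_ids = sorted(int(i) for i in window_ids)
    pairs = [(a, b) for a, b in zip(window_ids[:-1], window_ids[1:])]
    anchor_ids = sorted(set(int(i) for i in anchor_ids) - set(window_ids))
    if anchor_ids and poses is not None and plane is not None and K is not None:
        from .lba import project_footprint_centroid  # local import: avoid cycle

        if overlap_radius is None:
            overlap_radius = 0.75 * min(frame_size)
        cent = {
            i: project_footprint_centroid(poses[i], plane, K, frame_size)
            for i in set(window_ids) | set(anchor_ids)
        }
        for a in anchor_ids:
            for w in window_ids:
                if np.linalg.norm(cent[a] - cent[w]) < overlap_radius:
                    pairs.append((min(a, w), max(a, w)))
    seen, out = set(), []
    for p in pairs:
        if p not in seen and p[0] != p[1]:
            seen.add(p)
            out.append(p)
    return out
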