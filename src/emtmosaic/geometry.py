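"""Rotation/pose algebra, plane parametrization and plane-induced homographies.

Conventions used throughout the package
---------------------------------------

* A camera pose is the minimal 6-vector ``x = [r, t]`` with ``r`` an axis-angle
  rotation vector in so(3) (radians, ``|r| < pi``) and ``t`` a translation in mm.
* The scene plane is parametrized by the scaled normal ``pi = n / d`` (units
  1/mm), expressed in the reference (virtual) camera frame, with the unit
  normal ``n`` pointing from the plane toward the camera and ``d > 0`` the
  camera-to-plane distance, so on-plane 3-D points satisfy ``n . p = d``,
  i.e. ``pi . p = 1``.
* The homography induced by pose ``x`` and plane ``pi`` is

      ``H = K (R - t pi^T) K^{-1}``,   R = exp(r),

  and maps *mosaic-space* pixel coordinates (the image plane of a virtual
  camera at the origin) to pixel coordinates of the camera at ``x``.  Its
  inverse stitches an image into the mosaic.  Consistently, the rigid map
  from the reference frame into the camera frame is ``X_cam = R X - t``
  (extrinsics ``[R | -t]``), so the camera center is ``c = R^T t``.
* Pixels are 0-based, origin at the frame's top-left, x right / y down.
* Homographies are defined up to scale; the canonical representative has
  Frobenius norm 1 with positive bottom-right entry (fallback: the
  largest-magnitude entry is positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InfinitePointError

__all__ = [
    "Intrinsics",
    "Pose",
    "Plane",
    "Homography",
    "exp_so3",
    "log_so3",
    "pose_compose",
    "pose_inverse",
    "plane_homography",
    "pairwise_homography",
    "apply_homography",
    "chain_compose",
    "canonicalize",
    "plane_to_spherical",
    "spherical_to_plane",
    "pixel_to_normalized",
    "normalized_to_pixel",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics (zero skew): focal lengths and principal point, pixels."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not np.all(np.isfinite([self.fx, self.fy, self.cx, self.cy])):
            raise ValueError("intrinsics must be finite")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def inverse(self) -> np.ndarray:
        return np.array(
            [
                [1.0 / self.fx, 0.0, -self.cx / self.fx],
                [0.0, 1.0 / self.fy, -self.cy / self.fy],
                [0.0, 0.0, 1.0],
            ]
        )


@dataclass
class Pose:
    """A 6-DOF camera pose/measurement: rotation vector (rad) + translation (mm)."""

    r: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float).reshape(3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.r)) and np.all(np.isfinite(self.t))):
            raise ValueError("pose components must be finite")
        if np.linalg.norm(self.r) >= np.pi:
            raise ValueError("|r| must be < pi for a bijective rotation log")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.zeros(3), np.zeros(3))

    @classmethod
    def from_vector(cls, v) -> "Pose":
        v = np.asarray(v, dtype=float).reshape(6)
        return cls(v[:3], v[3:])

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.r, self.t])

    def matrix(self) -> np.ndarray:
        """The 4x4 rigid transform ``T = [R t; 0 1]`` of this parameter block."""
        T = np.eye(4)
        T[:3, :3] = exp_so3(self.r)
        T[:3, 3] = self.t
        return T

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "Pose":
        T = np.asarray(T, dtype=float)
        return cls(log_so3(T[:3, :3]), T[:3, 3])

    def copy(self) -> "Pose":
        return Pose(self.r.copy(), self.t.copy())


@dataclass
class Plane:
    """The scene plane as the scaled normal ``pi = n / d`` (1/mm)."""

    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.pi)):
            raise ValueError("plane vector must be finite")
        if np.linalg.norm(self.pi) <= 0:
            raise ValueError("plane vector must be nonzero")

    @classmethod
    def from_normal_distance(cls, n, d: float) -> "Plane":
        n = np.asarray(n, dtype=float).reshape(3)
        n = n / np.linalg.norm(n)
        if d <= 0:
            raise ValueError("plane distance must be positive")
        return cls(n / d)

    @property
    def normal(self) -> np.ndarray:
        return self.pi / np.linalg.norm(self.pi)

    @property
    def distance(self) -> float:
        return 1.0 / np.linalg.norm(self.pi)

    def copy(self) -> "Plane":
        return Plane(self.pi.copy())


def canonicalize(H: np.ndarray) -> np.ndarray:
    """Scale-canonical representative: Frobenius norm 1, sign fixed.

    Sign is chosen so the bottom-right entry is positive; when that entry is
    (numerically) zero the largest-magnitude entry is made positive instead.
    Idempotent bit-exactly: an already-canonical matrix is returned unchanged.
    """
    H = np.asarray(H, dtype=float)
    nrm = np.linalg.norm(H)
    if nrm == 0:
        raise ValueError("zero matrix cannot be canonicalized")
    if abs(H[2, 2]) > 1e-12 * nrm:
        sign = 1.0 if H[2, 2] > 0 else -1.0
    else:
        flat = H.ravel()
        pivot = flat[np.argmax(np.abs(flat))]
        sign = 1.0 if pivot > 0 else -1.0
    if abs(nrm - 1.0) < 1e-14 and sign > 0:
        return H
    return H * (sign / nrm)


@dataclass
class Homography:
    """A 3x3 projective map, stored in canonical scale."""

    H: np.ndarray

    def __post_init__(self):
        self.H = canonicalize(np.asarray(self.H, dtype=float).reshape(3, 3))
        if abs(np.linalg.det(self.H)) <= 1e-12:
            raise DegenerateGeometryError("homography is singular")

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @property
    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.H))

    def __matmul__(self, other: "Homography") -> "Homography":
        return Homography(self.H @ other.H)

    def apply(self, q) -> np.ndarray:
        return apply_homography(self, q)


# ---------------------------------------------------------------------------
# rotation algebra
# ---------------------------------------------------------------------------


def exp_so3(r) -> np.ndarray:
    """Exponential map so(3) -> SO(3) of a rotation vector."""
    r = np.asarray(r, dtype=float).reshape(3)
    if not np.all(np.isfinite(r)):
        raise ValueError("rotation vector must be finite")
    return Rotation.from_rotvec(r).as_matrix()


def log_so3(R) -> np.ndarray:
    """Logarithm SO(3) -> so(3); the returned vector has ``|r| <= pi``."""
    R = np.asarray(R, dtype=float).reshape(3, 3)
    if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-8 or np.linalg.det(R) < 0:
        raise ValueError("input is not a rotation matrix")
    return Rotation.from_matrix(R).as_rotvec()


def pose_compose(a: Pose, b: Pose) -> Pose:
    """The pose whose 4x4 matrix is ``a.matrix() @ b.matrix()``."""
    return Pose.from_matrix(a.matrix() @ b.matrix())


def pose_inverse(a: Pose) -> Pose:
    R = exp_so3(a.r)
    return Pose(log_so3(R.T), -R.T @ a.t)


# ---------------------------------------------------------------------------
# plane-induced homographies
# ---------------------------------------------------------------------------


def _plane_matrix(pose: Pose, plane: Plane, K: Intrinsics) -> np.ndarray:
    """Raw (uncanonicalized) ``K (R - t pi^T) K^{-1}``; internal hot-path helper."""
    R = exp_so3(pose.r)
    A = R - np.outer(pose.t, plane.pi)
    return K.matrix @ A @ K.inverse


def plane_homography(pose: Pose, plane: Plane, K: Intrinsics) -> Homography:
    """Homography mapping mosaic-space pixels to the pixels of camera ``pose``.

    Raises
    ------
    DegenerateGeometryError
        If the camera center lies on the plane (``R - t pi^T`` singular).
    """
    M = _plane_matrix(pose, plane, K)
    if abs(np.linalg.det(M)) <= 1e-12:
        raise DegenerateGeometryError("camera center lies on the scene plane")
    return Homography(M)


def pairwise_homography(x_k: Pose, x_km1: Pose, plane: Plane, K: Intrinsics) -> Homography:
    """``H_{k,k-1} = H_k H_{k-1}^{-1}``: maps image k-1 pixels into image k."""
    Hk = plane_homography(x_k, plane, K)
    Hkm1 = plane_homography(x_km1, plane, K)
    return Homography(Hk.H @ np.linalg.inv(Hkm1.H))


def apply_homography(H, q) -> np.ndarray:
    """Apply a homography to one point ``(2,)`` or a stack ``(N, 2)`` of points."""
    M = H.H if isinstance(H, Homography) else np.asarray(H, dtype=float)
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    pts = np.atleast_2d(q)
    hom = np.column_stack([pts, np.ones(len(pts))]) @ M.T
    denom = hom[:, 2]
    if np.any(np.abs(denom) <= 1e-12):
        raise InfinitePointError("point maps to infinity under this homography")
    out = hom[:, :2] / denom[:, None]
    return out[0] if single else out


def chain_compose(pairwise: list) -> Homography:
    """Left-multiplied product of pairwise homographies.

    ``pairwise`` is ordered ``[H_{k+1,k}, H_{k+2,k+1}, ..., H_{j,j-1}]`` and
    the result is ``H_{j,k} = H_{j,j-1} ... H_{k+1,k}``.
    """
    if len(pairwise) == 0:
        raise ValueError("chain_compose requires a non-empty list")
    M = np.eye(3)
    for h in pairwise:
        M = (h.H if isinstance(h, Homography) else np.asarray(h)) @ M
    return Homography(M)


# ---------------------------------------------------------------------------
# plane <-> spherical conversion (for reporting/plots)
# ---------------------------------------------------------------------------


def plane_to_spherical(plane: Plane) -> tuple[float, float, float]:
    """Return (azimuth deg, elevation deg, distance mm) of the plane.

    Convention: azimuth = atan2(n_y, n_x), elevation = asin(n_z), in degrees;
    distance = 1 / |pi|.
    """
    n = plane.normal
    azimuth = np.degrees(np.arctan2(n[1], n[0]))
    elevation = np.degrees(np.arcsin(np.clip(n[2], -1.0, 1.0)))
    return float(azimuth), float(elevation), float(plane.distance)


def spherical_to_plane(azimuth_deg: float, elevation_deg: float, distance_mm: float) -> Plane:
    az = np.radians(azimuth_deg)
    el = np.radians(elevation_deg)
    n = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    return Plane.from_normal_distance(n, distance_mm)


# ---------------------------------------------------------------------------
# pixel <-> normalized coordinates
# ---------------------------------------------------------------------------


def pixel_to_normalized(K: Intrinsics, q) -> np.ndarray:
    """``p = K^{-1} q~`` (dimensionless image coordinates)."""
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    pts = np.atleast_2d(q)
    out = np.column_stack([(pts[:, 0] - K.cx) / K.fx, (pts[:, 1] - K.cy) / K.fy])
    return out[0] if single else out


def normalized_to_pixel(K: Intrinsics, p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    out = np.column_stack([pts[:, 0] * K.fx + K.cx, pts[:, 1] * K.fy + K.cy])
    return out[0] if single else out
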