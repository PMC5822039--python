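"""Probabilistic fusion core: residual blocks, pairwise DLT, and batch solvers.

The maximum-a-posteriori estimate of camera poses ``X`` and plane ``pi``
given tracker measurements ``Z`` and correspondences is the minimizer of

    C(X, pi) = C_v + C_EMT + C_p

with a visual term (reprojection of each correspondence through the
plane-induced homography pair), a tracker term (per-axis Mahalanobis distance
of each measured pose to its latent pose, diagonal covariance), and a
constant-velocity motion prior (each pose against the extrapolation of its
two predecessors).  All three terms are exposed as weighted residual vectors
whose stacked sum of squares equals the cost, and are minimized jointly by
damped Gauss-Newton (Levenberg-Marquardt via ``scipy.optimize.least_squares``).

Visual residuals are evaluated in pixel space: points are conceptually
normalized through ``K^{-1}`` and re-projected through ``K`` so that
``sigma_v = 1 px`` is meaningful.  The number of correspondences in a pair
would otherwise swamp the tracker term (landmarks are modeled as independent
but are not); the default ``per-pair-count`` normalization divides each
pair's squared visual cost by its correspondence count, capping any single
pair's weight — a pragmatic correction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .correspondences import CorrespondenceCollection, CorrespondenceSet
from .errors import BrokenChainError, DegenerateGeometryError, InsufficientDataError
from .geometry import Homography, Intrinsics, Plane, Pose, canonicalize

__all__ = [
    "VisualNoiseModel",
    "EMTNoiseModel",
    "MotionModel",
    "ProblemState",
    "SolveOptions",
    "SolveReport",
    "predict_pose",
    "visual_residuals",
    "emt_residuals",
    "motion_prior_residuals",
    "estimate_pairwise_homography",
    "pairvis_chain",
    "solve_bundle",
    "estimate_motion_sigma",
]


# ---------------------------------------------------------------------------
# noise models and state
# ---------------------------------------------------------------------------


@dataclass
class VisualNoiseModel:
    """Correspondence noise std (px) and per-pair weight normalization policy."""

    sigma_v: float = 1.0
    normalization: str = "per-pair-count"  # {"none", "per-pair-count", "global-count"}

    def __post_init__(self):
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be positive")
        if self.normalization not in ("none", "per-pair-count", "global-count"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class EMTNoiseModel:
    """Diagonal tracker covariance as a 6-vector of variances (rad^2, mm^2)."""

    variances: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [np.full(3, np.radians(1.0) ** 2), np.full(3, 1.0)]
        )
    )

    def __post_init__(self):
        self.variances = np.asarray(self.variances, dtype=float).reshape(6)
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @classmethod
    def from_sigmas(cls, sigma_rot_deg: float, sigma_trans_mm: float) -> "EMTNoiseModel":
        return cls(np.concatenate([
            np.full(3, np.radians(sigma_rot_deg) ** 2),
            np.full(3, sigma_trans_mm**2),
        ]))


@dataclass
class MotionModel:
    """Diagonal covariance of the constant-velocity prior (rad^2, mm^2)."""

    variances: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [np.full(3, np.radians(0.5) ** 2), np.full(3, 1.0)]
        )
    )

    def __post_init__(self):
        self.variances = np.asarray(self.variances, dtype=float).reshape(6)
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @classmethod
    def from_sigmas(cls, sigma_rot_deg: float, sigma_trans_mm: float) -> "MotionModel":
        return cls(np.concatenate([
            np.full(3, np.radians(sigma_rot_deg) ** 2),
            np.full(3, sigma_trans_mm**2),
        ]))


@dataclass
class ProblemState:
    """Poses, plane, and which poses are free to be optimized."""

    poses: list
    plane: Plane
    free_mask: np.ndarray = None
    free_plane: bool = True

    def __post_init__(self):
        if self.free_mask is None:
            self.free_mask = np.ones(len(self.poses), dtype=bool)
        self.free_mask = np.asarray(self.free_mask, dtype=bool).reshape(len(self.poses))
        if not (self.free_mask.any() or self.free_plane):
            raise ValueError("at least one pose or the plane must be free")

    def pose_array(self) -> np.ndarray:
        return np.array([p.as_vector() for p in self.poses])

    def copy(self) -> "ProblemState":
        return ProblemState(
            [p.copy() for p in self.poses], self.plane.copy(),
            self.free_mask.copy(), self.free_plane,
        )


@dataclass
class SolveOptions:
    intrinsics: Intrinsics | None = None
    max_iter: int = 100
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    plane_mode: str = "full"  # "full" (3 dof) or "direction" (2 dof, d clamped)
    use_motion_prior: bool = True
    emt_ids: list | None = None  # pose indices carrying a tracker residual
    prior_ks: list | None = None  # pose indices k carrying a prior residual


@dataclass
class SolveReport:
    converged: bool
    iterations: int
    initial_cost: float
    final_cost: float
    cost_terms: dict


# ---------------------------------------------------------------------------
# constant-velocity prediction
# ---------------------------------------------------------------------------


def predict_pose(x_km1: Pose, x_km2: Pose) -> Pose:
    """Extrapolate one step at constant velocity.

    The predicted rigid transform is ``T = (T_{k-1} T_{k-2}^{-1}) T_{k-1}``:
    the last pose composed with the last available pairwise velocity.
    """
    T1, T2 = x_km1.matrix(), x_km2.matrix()
    return Pose.from_matrix(T1 @ np.linalg.inv(T2) @ T1)


# ---------------------------------------------------------------------------
# fast residual evaluation on raw arrays
# ---------------------------------------------------------------------------


def _batch_matrices(pose_arr: np.ndarray) -> np.ndarray:
    """(N, 6) pose rows -> (N, 4, 4) rigid matrices."""
    n = len(pose_arr)
    T = np.tile(np.eye(4), (n, 1, 1))
    if n:
        T[:, :3, :3] = Rotation.from_rotvec(pose_arr[:, :3]).as_matrix()
        T[:, :3, 3] = pose_arr[:, 3:]
    return T


def _pair_weight(count: int, model: VisualNoiseModel, total: int) -> float:
    if model.normalization == "none":
        c = 1.0
    elif model.normalization == "per-pair-count":
        c = float(count)
    else:  # global-count
        c = float(total)
    return 1.0 / (model.sigma_v * np.sqrt(c))


class _VisualBlock:
    """Precompiled visual residual block for repeated evaluation."""

    def __init__(self, corrs: CorrespondenceCollection, model: VisualNoiseModel,
                 K: Intrinsics):
        self.K = K.matrix
        self.K_inv = K.inverse
        total = corrs.total_points()
        self.pairs = []
        for s in corrs.sets():
            if len(s) == 0:
                continue
            qa_h = np.column_stack([s.points_a, np.ones(len(s))])
            self.pairs.append((s.pair, qa_h, s.points_b, _pair_weight(len(s), model, total)))
        self.ids = sorted({i for (m, l), *_ in self.pairs for i in (m, l)})
        self._pos = {i: k for k, i in enumerate(self.ids)}
        self.size = 2 * sum(len(qb) for _, _, qb, _ in self.pairs)

    def __call__(self, pose_arr: np.ndarray, pi: np.ndarray) -> np.ndarray:
        if not self.pairs:
            return np.zeros(0)
        sub = pose_arr[self.ids]
        R = Rotation.from_rotvec(sub[:, :3]).as_matrix()
        A = R - sub[:, 3:, None] * pi[None, None, :]
        M = self.K[None] @ A @ self.K_inv[None]
        det = np.linalg.det(M)
        if np.any(np.abs(det) <= 1e-12):
            raise DegenerateGeometryError("degenerate homography inside visual term")
        M_inv = np.linalg.inv(M)
        out = []
        for (m, l), qa_h, qb, wgt in self.pairs:
            H = M[self._pos[l]] @ M_inv[self._pos[m]]
            proj = qa_h @ H.T
            pred = proj[:, :2] / proj[:, 2:3]
            out.append(((qb - pred) * wgt).ravel())
        return np.concatenate(out)


def visual_residuals(state: ProblemState, corrs: CorrespondenceCollection,
                     model: VisualNoiseModel, K: Intrinsics) -> np.ndarray:
    """Weighted reprojection residuals, one (x, y) pair per correspondence.

    Residual i of pair (m, l) is ``(p_B^i - mu_v(x_l, x_m, pi, p_A^i)) * w``
    in pixels, with ``w = 1 / (sigma_v sqrt(c))`` and ``c`` the normalization
    count; the sum of squares is the visual cost C_v under the policy.
    """
    block = _VisualBlock(corrs, model, K)
    return block(state.pose_array(), state.plane.pi)


def emt_residuals(state: ProblemState, Z, model: EMTNoiseModel,
                  ids=None) -> np.ndarray:
    """Per-frame weighted tracker residuals ``Sigma^{-1/2} (z_k - x_k)``.

    ``Z`` is aligned with ``ids`` (default: every pose in the state).  The
    rotation difference is taken componentwise on the rotation vectors.
    """
    ids = list(range(len(state.poses))) if ids is None else list(ids)
    if len(Z) != len(ids):
        raise ValueError("one measurement per pose with an EMT term required")
    inv_sigma = 1.0 / np.sqrt(model.variances)
    pose_arr = state.pose_array()
    z_arr = np.array([z.as_vector() for z in Z])
    return ((z_arr - pose_arr[ids]) * inv_sigma[None, :]).ravel()


def _prior_residuals_arr(pose_arr: np.ndarray, ks, inv_sigma: np.ndarray) -> np.ndarray:
    """Constant-velocity residuals on a raw (N, 6) pose array (hot path)."""
    if not ks:
        return np.zeros(0)
    ids = sorted({i for k in ks for i in (k, k - 1, k - 2)})
    pos = {i: j for j, i in enumerate(ids)}
    T = _batch_matrices(pose_arr[ids])
    T_inv = np.linalg.inv(T)
    out = np.empty((len(ks), 6))
    mu_R = np.empty((len(ks), 3, 3))
    for j, k in enumerate(ks):
        Tbar = T[pos[k - 1]] @ T_inv[pos[k - 2]] @ T[pos[k - 1]]
        mu_R[j] = Tbar[:3, :3]
        out[j, 3:] = pose_arr[k, 3:] - Tbar[:3, 3]
    mu_r = Rotation.from_matrix(mu_R).as_rotvec()
    out[:, :3] = pose_arr[ks, :3] - mu_r
    return (out * inv_sigma[None, :]).ravel()


def motion_prior_residuals(state: ProblemState, model: MotionModel,
                           ks=None) -> np.ndarray:
    """Weighted constant-velocity residuals ``Sigma_p^{-1/2}(x_k - mu_p)``.

    By default one residual per pose index ``k >= 2``; for windowed problems
    pass the estimated indices as ``ks`` — predecessors may be fixed cameras,
    which yields the two boundary terms linking into the fixed set.
    """
    n = len(state.poses)
    ks = [k for k in range(2, n)] if ks is None else [k for k in ks if k >= 2]
    inv_sigma = 1.0 / np.sqrt(model.variances)
    return _prior_residuals_arr(state.pose_array(), ks, inv_sigma)


# ---------------------------------------------------------------------------
# pairwise homography estimation (DLT + LM) and the chained baseline
# ---------------------------------------------------------------------------


def _normalize_points(pts: np.ndarray):
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])
    return (pts - centroid) * s, T


def estimate_pairwise_homography(corr: CorrespondenceSet, refine: bool = True) -> Homography:
    """Normalized DLT (Hartley preconditioning) + optional LM refinement.

    Refinement minimizes the symmetric transfer error.  Requires at least
    four non-collinear correspondences.
    """
    if len(corr) < 4:
        raise InsufficientDataError(f"{len(corr)} correspondences; need >= 4")
    pa, pb = corr.points_a, corr.points_b
    na, Ta = _normalize_points(pa)
    nb, Tb = _normalize_points(pb)
    n = len(pa)
    A = np.zeros((2 * n, 9))
    x, y = na[:, 0], na[:, 1]
    u, v = nb[:, 0], nb[:, 1]
    A[0::2, 0], A[0::2, 1], A[0::2, 2] = -x, -y, -1.0
    A[0::2, 6], A[0::2, 7], A[0::2, 8] = u * x, u * y, u
    A[1::2, 3], A[1::2, 4], A[1::2, 5] = -x, -y, -1.0
    A[1::2, 6], A[1::2, 7], A[1::2, 8] = v * x, v * y, v
    _, sv, Vt = np.linalg.svd(A)
    if sv[-2] <= 1e-9 * sv[0]:
        raise InsufficientDataError("correspondences are (near-)collinear")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Tb) @ Hn @ Ta
    H = canonicalize(H)

    if refine and n > 4:
        ones = np.ones(n)
        pa_h = np.column_stack([pa, ones])
        pb_h = np.column_stack([pb, ones])

        def resid(h):
            M = h.reshape(3, 3)
            try:
                Mi = np.linalg.inv(M)
            except np.linalg.LinAlgError:
                return np.full(4 * n, 1e6)
            f = pa_h @ M.T
            b = pb_h @ Mi.T
            with np.errstate(divide="ignore", invalid="ignore"):
                rf = pb - f[:, :2] / f[:, 2:3]
                rb = pa - b[:, :2] / b[:, 2:3]
            r = np.concatenate([rf.ravel(), rb.ravel()])
            return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=1e6)

        sol = least_squares(resid, H.ravel(), method="lm", xtol=1e-14, ftol=1e-14)
        H = canonicalize(sol.x.reshape(3, 3))
    return Homography(H)


def pairvis_chain(corrs: CorrespondenceCollection, n_frames: int) -> list:
    """The drifting baseline: chain DLT-estimated adjacent homographies.

    Returns mosaic-to-image homographies ``H_j`` with ``H_0 = I``.  A missing
    adjacent pair breaks the chain of transformations and raises
    :class:`BrokenChainError` naming the gap.
    """
    Hs = [Homography.identity()]
    for k in range(1, n_frames):
        s = corrs.get(k - 1, k)
        if s is None or len(s) < 4:
            raise BrokenChainError((k - 1, k))
        H_pair = estimate_pairwise_homography(s)
        Hs.append(Homography(H_pair.H @ Hs[-1].H))
    return Hs


# ---------------------------------------------------------------------------
# joint solver
# ---------------------------------------------------------------------------


def _plane_pack(plane: Plane, mode: str) -> np.ndarray:
    if mode == "full":
        return plane.pi.copy()
    n = plane.normal
    return np.array([np.arctan2(n[1], n[0]), np.arcsin(np.clip(n[2], -1, 1))])


def _plane_unpack(params: np.ndarray, mode: str, d0: float) -> np.ndarray:
    if mode == "full":
        return params
    az, el = params
    n = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    return n / d0


def solve_bundle(state: ProblemState, corrs: CorrespondenceCollection,
                 Z=None, visual_model: VisualNoiseModel | None = None,
                 emt_model: EMTNoiseModel | None = None,
                 motion_model: MotionModel | None = None,
                 options: SolveOptions | None = None):
    """Minimize the stacked weighted residuals over the free poses and plane.

    ``Z is None`` gives pure visual bundle adjustment (the caller is
    responsible for gauge fixing: clamp one pose via ``free_mask`` and the
    plane depth via ``options.plane_mode='direction'``); with measurements the
    tracker term makes the problem fully constrained and ``Z`` also serves as
    the natural initialization.  Returns ``(new_state, SolveReport)``.
    """
    options = options or SolveOptions()
    visual_model = visual_model or VisualNoiseModel()
    state0 = state.copy()
    pose_arr = state0.pose_array()
    free_ids = np.flatnonzero(state0.free_mask)
    n_pose_params = 6 * len(free_ids)
    d0 = state0.plane.distance

    vis = _VisualBlock(corrs, visual_model, _require_intrinsics(options))
    emt_ids = options.emt_ids
    if Z is not None:
        emt_model = emt_model or EMTNoiseModel()
        emt_ids = list(range(len(state0.poses))) if emt_ids is None else list(emt_ids)
        z_arr = np.array([z.as_vector() for z in Z])
        inv_sigma_emt = 1.0 / np.sqrt(emt_model.variances)
    use_prior = options.use_motion_prior and motion_model is not None
    if use_prior:
        n = len(state0.poses)
        prior_ks = (
            [k for k in range(2, n)] if options.prior_ks is None
            else [k for k in options.prior_ks if k >= 2]
        )
        use_prior = len(prior_ks) > 0
        inv_sigma_p = 1.0 / np.sqrt(motion_model.variances)

    def unpack(params):
        pa = pose_arr.copy()
        if n_pose_params:
            pa[free_ids] = params[:n_pose_params].reshape(-1, 6)
        if state0.free_plane:
            pi = _plane_unpack(params[n_pose_params:], options.plane_mode, d0)
        else:
            pi = state0.plane.pi
        return pa, pi

    def residuals(params):
        pa, pi = unpack(params)
        parts = [vis(pa, pi)]
        if Z is not None:
            parts.append(((z_arr - pa[emt_ids]) * inv_sigma_emt[None, :]).ravel())
        if use_prior:
            parts.append(_prior_residuals_arr(pa, prior_ks, inv_sigma_p))
        return np.concatenate(parts)

    x0 = []
    if n_pose_params:
        x0.append(pose_arr[free_ids].ravel())
    if state0.free_plane:
        x0.append(_plane_pack(state0.plane, options.plane_mode))
    x0 = np.concatenate(x0)

    r0 = residuals(x0)
    if not np.all(np.isfinite(r0)):
        raise ValueError("non-finite residuals at initialization")
    initial_cost = float(r0 @ r0)

    sol = least_squares(
        residuals, x0, method="trf", x_scale="jac",
        ftol=options.ftol, xtol=options.xtol, gtol=options.gtol,
        max_nfev=options.max_iter * (len(x0) + 1),
    )
    x_best = sol.x if 2 * sol.cost <= initial_cost else x0
    pa, pi = unpack(x_best)
    new_state = ProblemState(
        [Pose.from_vector(v) for v in pa], Plane(pi),
        state0.free_mask.copy(), state0.free_plane,
    )

    # final per-term costs
    r_v = vis(pa, pi)
    terms = {"C_v": float(r_v @ r_v), "C_EMT": 0.0, "C_p": 0.0}
    if Z is not None:
        r_e = ((z_arr - pa[emt_ids]) * inv_sigma_emt[None, :]).ravel()
        terms["C_EMT"] = float(r_e @ r_e)
    if use_prior:
        r_p = motion_prior_residuals(new_state, motion_model, prior_ks)
        terms["C_p"] = float(r_p @ r_p)
    final_cost = sum(terms.values())
    report = SolveReport(
        converged=bool(sol.status > 0),
        iterations=int(sol.nfev),
        initial_cost=initial_cost,
        final_cost=final_cost,
        cost_terms=terms,
    )
    return new_state, report


def _require_intrinsics(options) -> Intrinsics:
    K = getattr(options, "intrinsics", None)
    if K is None:
        raise ValueError("SolveOptions.intrinsics must be set for the visual term")
    return K


def estimate_motion_sigma(poses) -> np.ndarray:
    """Per-axis std of constant-velocity residuals on a trajectory.

    Utility for calibrating the motion prior from a held-out trajectory with
    motion characteristics similar to the target sequence.
    """
    st = ProblemState([p.copy() for p in poses], Plane([0, 0, 1.0 / 50]),
                      np.ones(len(poses), bool), True)
    unit = MotionModel(np.ones(6))
    r = motion_prior_residuals(st, unit).reshape(-1, 6)
    return r.std(axis=0)
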