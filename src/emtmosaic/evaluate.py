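"""Drift metrics and the scripted synthetic experiments.

A mosaic is a collection of mosaic-to-image homographies, so comparing an
estimated mosaic with the truth reduces to comparing homography collections:
the per-frame error ``e_j`` is the mean Euclidean distance, in mosaic space,
between a regular grid of frame points projected through the estimated
``H_j^{-1}`` and through the ground-truth ``H_{j,GT}^{-1}``; the mosaic
error ``e_M`` is the mean of the ``e_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BrokenChainError
from .estimators import BundleAdjustmentMosaicker, PairwiseChainMosaicker, SlidingWindowMosaicker
from .fusion import estimate_motion_sigma
from .geometry import Homography, Intrinsics, Plane, apply_homography, plane_homography
from .synthetic import (
    EMTNoiseConfig,
    SceneConfig,
    SyntheticCorrespondenceProvider,
    blank_frames,
    make_sequence,
)

__all__ = [
    "ErrorReport",
    "frame_error",
    "mosaic_error",
    "evaluate_homographies",
    "emt_only_composition",
    "DriftConfig",
    "DriftResult",
    "run_drift_experiment",
    "SweepConfig",
    "run_noise_sweep",
    "DropoutConfig",
    "DropoutResult",
    "run_dropout_experiment",
    "DEFAULT_DROPOUT_INDICES",
]

# default blanked-frame indices for the 62-frame dropout experiment
DEFAULT_DROPOUT_INDICES = (7, 11, 12, 23, 24, 37, 38, 42, 43, 45, 51, 54)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class ErrorReport:
    per_frame: np.ndarray
    n_grid: int
    frame_size: tuple

    @property
    def e_M(self) -> float:
        return float(np.mean(self.per_frame))


def _frame_grid(frame_size, n_grid: int) -> np.ndarray:
    w, h = frame_size
    xs = np.linspace(0.0, w - 1.0, n_grid)
    ys = np.linspace(0.0, h - 1.0, n_grid)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def frame_error(H: Homography, H_gt: Homography, frame_size, n_grid: int = 100) -> float:
    """Mean mosaic-space residual of a regular n_grid x n_grid point lattice.

    Both homographies map mosaic space to the image; the grid spans the frame
    (corners included) and is pushed into mosaic space through the inverses.
    Invariant to the arbitrary scale of either homography.
    """
    grid = _frame_grid(frame_size, n_grid)
    a = apply_homography(np.linalg.inv(H.H), grid)
    b = apply_homography(np.linalg.inv(H_gt.H), grid)
    return float(np.linalg.norm(a - b, axis=1).mean())


def mosaic_error(errors) -> float:
    """Arithmetic mean of per-frame errors (the mosaic's average error, px)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("mosaic_error requires at least one frame error")
    return float(errors.mean())


def evaluate_homographies(homographies, gt_homographies, frame_size,
                          n_grid: int = 100) -> ErrorReport:
    errs = np.array([
        frame_error(H, H_gt, frame_size, n_grid)
        for H, H_gt in zip(homographies, gt_homographies)
    ])
    return ErrorReport(errs, n_grid, tuple(frame_size))


def emt_only_composition(Z, plane_gt: Plane, K: Intrinsics) -> list:
    """The jittery baseline: homographies straight from the raw measurements
    and the ground-truth plane (no estimation)."""
    return [plane_homography(z, plane_gt, K) for z in Z]


# ---------------------------------------------------------------------------
# experiment protocols
# ---------------------------------------------------------------------------


def _matched_lba(nu: float, sigma_v: float, seed: int, **kw) -> SlidingWindowMosaicker:
    """Sequencer whose tracker covariance matches the dataset's noise scale."""
    s = max(nu, 1e-4)
    return SlidingWindowMosaicker(
        sigma_v=max(sigma_v, 1e-4),
        sigma_emt_rot_deg=s, sigma_emt_trans_mm=s, seed=seed, **kw,
    )


@dataclass
class DriftConfig:
    """150 circular frames, sigma_v = 1 px, nu = 1 — the drift dichotomy setup."""

    n_frames: int = 150
    laps: float = 3.0
    radius_mm: float = 40.0
    sigma_v: float = 1.0
    nu: float = 1.0
    n_points: int = 50
    seed: int = 0
    n_grid: int = 100
    include_batch: bool | None = None  # default: only for short sequences


@dataclass
class DriftResult:
    curves: dict  # method -> per-frame e_j array
    e_M: dict
    slopes: dict  # method -> (slope px/frame, two-sided p-value)
    bounded: dict  # method -> max(e_j last third) <= 2 * max(e_j first third)
    errors: dict = field(default_factory=dict)  # method -> raised error repr


def _slope(e_j: np.ndarray):
    fit = stats.linregress(np.arange(len(e_j)), e_j)
    return float(fit.slope), float(fit.pvalue)


def _bounded(e_j: np.ndarray) -> bool:
    third = len(e_j) // 3
    return float(np.max(e_j[-third:])) <= 2.0 * float(np.max(e_j[:third]))


def run_drift_experiment(config: DriftConfig | None = None) -> DriftResult:
    """PairVis vs the sequencer (and optionally batch BA) on one noisy run."""
    config = config or DriftConfig()
    scene = SceneConfig(n_frames=config.n_frames, laps=config.laps,
                        radius_mm=config.radius_mm, seed=config.seed)
    seq = make_sequence(
        scene, EMTNoiseConfig(nu=config.nu, seed=config.seed),
        sigma_v=config.sigma_v, n_points=config.n_points,
    )
    gt = seq.ground_truth.gt_homographies
    curves, e_M, slopes, bounded, errors = {}, {}, {}, {}, {}

    def record(name, homos):
        rep = evaluate_homographies(homos, gt, seq.frame_size, config.n_grid)
        curves[name] = rep.per_frame
        e_M[name] = rep.e_M
        slopes[name] = _slope(rep.per_frame)
        bounded[name] = _bounded(rep.per_frame)

    provider = SyntheticCorrespondenceProvider(
        seq, n_points=config.n_points, sigma_v=config.sigma_v, seed=config.seed)
    try:
        record("pairvis", PairwiseChainMosaicker().fit(seq).homographies_)
    except BrokenChainError as exc:  # pragma: no cover - only with dropout input
        errors["pairvis"] = repr(exc)
    record("lba_vis_emt", _matched_lba(config.nu, config.sigma_v, config.seed)
           .fit(seq, provider=provider).homographies_)
    include_batch = (
        config.include_batch if config.include_batch is not None
        else config.n_frames <= 40
    )
    if include_batch:
        record("ba_vis_emt", BundleAdjustmentMosaicker(
            sigma_emt_rot_deg=max(config.nu, 1e-4),
            sigma_emt_trans_mm=max(config.nu, 1e-4),
        ).fit(seq).homographies_)
        record("ba_vis", BundleAdjustmentMosaicker(use_emt=False).fit(seq).homographies_)
    return DriftResult(curves, e_M, slopes, bounded, errors)


@dataclass
class SweepConfig:
    """Seventeen-frame sequences across a seven-value tracker-noise grid."""

    nu_values: tuple = (0.125, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0)
    n_frames: int = 17
    laps: float = 0.34
    radius_mm: float = 40.0
    sigma_v: float = 1.0
    n_points: int = 50
    seed: int = 0
    n_grid: int = 100
    flatness_bound: float = 2.0


def run_noise_sweep(config: SweepConfig | None = None) -> pd.DataFrame:
    """Fusion vs tracker-only error across the noise grid.

    The scene geometry and correspondences are shared across cells; each cell
    draws fresh tracker noise from its own seeded stream.  Returns a table
    with one row per ``nu``.
    """
    config = config or SweepConfig()
    scene = SceneConfig(n_frames=config.n_frames, laps=config.laps,
                        radius_mm=config.radius_mm, seed=config.seed)
    rows = []
    for i, nu in enumerate(config.nu_values):
        emt_cfg = EMTNoiseConfig(nu=float(nu), seed=config.seed + 101 * i)
        seq = make_sequence(scene, emt_cfg, sigma_v=config.sigma_v,
                            n_points=config.n_points)
        gt = seq.ground_truth.gt_homographies
        provider = SyntheticCorrespondenceProvider(
            seq, n_points=config.n_points, sigma_v=config.sigma_v, seed=config.seed)
        fusion = _matched_lba(float(nu), config.sigma_v, config.seed).fit(
            seq, provider=provider)
        e_fusion = evaluate_homographies(
            fusion.homographies_, gt, seq.frame_size, config.n_grid).e_M
        emt_h = emt_only_composition(seq.emt, seq.ground_truth.plane, seq.intrinsics)
        e_emt = evaluate_homographies(emt_h, gt, seq.frame_size, config.n_grid).e_M
        rows.append({"nu": float(nu), "e_M_fusion": e_fusion, "e_M_emt_only": e_emt})
    df = pd.DataFrame(rows)
    df.attrs["emt_only_monotone"] = bool(df["e_M_emt_only"].is_monotonic_increasing)
    df.attrs["fusion_flatness_ratio"] = float(
        df["e_M_fusion"].max() / max(df["e_M_fusion"].min(), 1e-12))
    df.attrs["flatness_bound"] = config.flatness_bound
    return df


@dataclass
class DropoutConfig:
    """62-frame run with twelve frames blacked out (visual-loss robustness)."""

    n_frames: int = 62
    laps: float = 1.24
    radius_mm: float = 40.0
    sigma_v: float = 1.0
    nu: float = 1.0
    n_points: int = 50
    indices: tuple = DEFAULT_DROPOUT_INDICES
    seed: int = 0
    n_grid: int = 100


@dataclass
class DropoutResult:
    e_M_dropout: float
    e_M_clean: float
    ratio: float
    n_poses: int
    pairvis_broken: bool
    plane_trace: list
    poses: list
    per_frame: np.ndarray


def run_dropout_experiment(config: DropoutConfig | None = None) -> DropoutResult:
    """Blank the configured frames, rerun the sequencer, compare to the clean run."""
    config = config or DropoutConfig()
    scene = SceneConfig(n_frames=config.n_frames, laps=config.laps,
                        radius_mm=config.radius_mm, seed=config.seed)
    clean = make_sequence(scene, EMTNoiseConfig(nu=config.nu, seed=config.seed),
                          sigma_v=config.sigma_v, n_points=config.n_points)
    dropped = blank_frames(clean, config.indices)
    gt = clean.ground_truth.gt_homographies

    prov_drop = SyntheticCorrespondenceProvider(
        dropped, n_points=config.n_points, sigma_v=config.sigma_v, seed=config.seed)
    prov_clean = SyntheticCorrespondenceProvider(
        clean, n_points=config.n_points, sigma_v=config.sigma_v, seed=config.seed)
    fit_drop = _matched_lba(config.nu, config.sigma_v, config.seed).fit(
        dropped, provider=prov_drop)
    fit_clean = _matched_lba(config.nu, config.sigma_v, config.seed).fit(
        clean, provider=prov_clean)
    rep_drop = evaluate_homographies(fit_drop.homographies_, gt,
                                     clean.frame_size, config.n_grid)
    rep_clean = evaluate_homographies(fit_clean.homographies_, gt,
                                      clean.frame_size, config.n_grid)
    try:
        PairwiseChainMosaicker().fit(dropped)
        broken = False
    except BrokenChainError:
        broken = True
    return DropoutResult(
        e_M_dropout=rep_drop.e_M,
        e_M_clean=rep_clean.e_M,
        ratio=rep_drop.e_M / max(rep_clean.e_M, 1e-12),
        n_poses=sum(p is not None for p in fit_drop.poses_),
        pairvis_broken=broken,
        plane_trace=fit_drop.plane_trace_,
        poses=fit_drop.poses_,
        per_frame=rep_drop.per_frame,
    )
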