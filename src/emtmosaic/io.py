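"""File formats and sequence loading.

All on-disk formats are plain text or PNG:

* intrinsics — JSON/YAML ``{fx, fy, cx, cy}`` (px)
* poses / EMT — CSV ``frame, rx, ry, rz, tx, ty, tz`` (radians, mm)
* plane — JSON ``{"pi": [px, py, pz]}`` (1/mm)
* homographies — CSV ``frame, h11..h33`` (row-major)
* correspondences — CSV ``m, l, xa, ya, xb, yb`` (one match per row, px)
* frames — ``frames/frame_<k>.png``
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .correspondences import CorrespondenceCollection, CorrespondenceSet
from .errors import AlignmentError, SchemaError
from .geometry import Homography, Intrinsics, Plane, Pose

POSE_COLUMNS = ["frame", "rx", "ry", "rz", "tx", "ty", "tz"]
HOMOGRAPHY_COLUMNS = ["frame"] + [f"h{i}{j}" for i in range(1, 4) for j in range(1, 4)]
CORRESPONDENCE_COLUMNS = ["m", "l", "xa", "ya", "xb", "yb"]


# ---------------------------------------------------------------------------
# atoms
# ---------------------------------------------------------------------------


def save_intrinsics(path, K: Intrinsics) -> None:
    data = {"fx": K.fx, "fy": K.fy, "cx": K.cx, "cy": K.cy}
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_intrinsics(path) -> Intrinsics:
    path = Path(path)
    raw = path.read_text()
    try:
        data = yaml.safe_load(raw) if path.suffix in (".yaml", ".yml") else json.loads(raw)
        return Intrinsics(**{k: float(data[k]) for k in ("fx", "fy", "cx", "cy")})
    except (KeyError, TypeError, ValueError, yaml.YAMLError) as exc:
        raise SchemaError(f"bad intrinsics file {path}: {exc}") from exc


def save_poses(path, poses, frames=None) -> None:
    frames = range(len(poses)) if frames is None else frames
    rows = [
        {"frame": int(f), "rx": p.r[0], "ry": p.r[1], "rz": p.r[2],
         "tx": p.t[0], "ty": p.t[1], "tz": p.t[2]}
        for f, p in zip(frames, poses)
    ]
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(path, index=False)


def load_poses(path) -> tuple[list, list]:
    """Returns (frame indices, poses) sorted by frame index."""
    df = pd.read_csv(path)
    if list(df.columns) != POSE_COLUMNS:
        raise SchemaError(f"pose CSV {path} must have columns {POSE_COLUMNS}")
    df = df.sort_values("frame")
    poses = [Pose(row[1:4].to_numpy(float), row[4:7].to_numpy(float))
             for _, row in df.iterrows()]
    return df["frame"].astype(int).tolist(), poses


def save_plane(path, plane: Plane) -> None:
    Path(path).write_text(json.dumps({"pi": plane.pi.tolist()}, indent=2))


def load_plane(path) -> Plane:
    try:
        return Plane(json.loads(Path(path).read_text())["pi"])
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise SchemaError(f"bad plane file {path}: {exc}") from exc


def save_homographies(path, homographies, frames=None) -> None:
    frames = range(len(homographies)) if frames is None else frames
    rows = []
    for f, H in zip(frames, homographies):
        M = H.H if isinstance(H, Homography) else np.asarray(H)
        rows.append([int(f), *M.ravel().tolist()])
    pd.DataFrame(rows, columns=HOMOGRAPHY_COLUMNS).to_csv(path, index=False)


def load_homographies(path) -> tuple[list, list]:
    df = pd.read_csv(path)
    if list(df.columns) != HOMOGRAPHY_COLUMNS:
        raise SchemaError(f"homography CSV {path} must have columns {HOMOGRAPHY_COLUMNS}")
    df = df.sort_values("frame")
    Hs = [Homography(row[1:].to_numpy(float).reshape(3, 3)) for _, row in df.iterrows()]
    return df["frame"].astype(int).tolist(), Hs


def save_correspondences(path, collection: CorrespondenceCollection) -> None:
    rows = []
    for s in collection.sets():
        m, l = s.pair
        for (xa, ya), (xb, yb) in zip(s.points_a, s.points_b):
            rows.append([m, l, xa, ya, xb, yb])
    pd.DataFrame(rows, columns=CORRESPONDENCE_COLUMNS).to_csv(path, index=False)


def load_correspondences(path) -> CorrespondenceCollection:
    df = pd.read_csv(path)
    if list(df.columns) != CORRESPONDENCE_COLUMNS:
        raise SchemaError(
            f"correspondence CSV {path} must have columns {CORRESPONDENCE_COLUMNS}")
    coll = CorrespondenceCollection()
    for (m, l), grp in df.groupby(["m", "l"], sort=True):
        coll.add(CorrespondenceSet(
            (int(m), int(l)),
            grp[["xa", "ya"]].to_numpy(float),
            grp[["xb", "yb"]].to_numpy(float),
        ))
    return coll


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


@dataclass
class SequenceData:
    """A loaded acquisition, shaped like a synthetic sequence (minus the truth)."""

    emt: list | None
    correspondences: CorrespondenceCollection
    intrinsics: Intrinsics
    frame_size: tuple
    frames: list | None = None
    frame_ids: list | None = None

    @property
    def n_frames(self) -> int:
        if self.frame_ids is not None:
            return len(self.frame_ids)
        return len(self.emt) if self.emt is not None else len(self.frames)


def _apply_hand_eye(poses, hand_eye: np.ndarray) -> list:
    """Right-multiply each raw sensor pose by the fixed sensor-to-camera transform."""
    he = np.asarray(hand_eye, dtype=float).reshape(4, 4)
    return [Pose.from_matrix(p.matrix() @ he) for p in poses]


def load_sequence(emt_csv=None, intrinsics_path=None, frames_dir=None,
                  correspondences_csv=None, hand_eye=None) -> SequenceData:
    """Load an acquisition directory, aligning frames and measurements by index.

    A frame index present in only one of the sources raises
    :class:`AlignmentError` listing the offending indices.
    """
    if intrinsics_path is None:
        raise SchemaError("intrinsics are required")
    K = load_intrinsics(intrinsics_path)
    emt_ids, emt = (None, None)
    if emt_csv is not None:
        emt_ids, emt = load_poses(emt_csv)
        if hand_eye is not None:
            emt = _apply_hand_eye(emt, hand_eye)
    frames, frame_ids = None, None
    if frames_dir is not None:
        paths = sorted(Path(frames_dir).glob("frame_*.png"),
                       key=lambda p: int(p.stem.split("_")[1]))
        frame_ids = [int(p.stem.split("_")[1]) for p in paths]
        frames = [iio.imread(p) for p in paths]
    if emt_ids is not None and frame_ids is not None:
        missing_f = sorted(set(emt_ids) - set(frame_ids))
        missing_z = sorted(set(frame_ids) - set(emt_ids))
        if missing_f or missing_z:
            raise AlignmentError(
                f"frames missing for EMT rows {missing_f}; "
                f"EMT rows missing for frames {missing_z}")
    corrs = (load_correspondences(correspondences_csv)
             if correspondences_csv is not None else CorrespondenceCollection())
    if frames is not None:
        h, w = np.asarray(frames[0]).shape[:2]
        frame_size = (w, h)
    else:
        frame_size = (int(2 * K.cx + 1), int(2 * K.cy + 1))
    return SequenceData(
        emt=emt, correspondences=corrs, intrinsics=K,
        frame_size=frame_size, frames=frames,
        frame_ids=frame_ids if frame_ids is not None else emt_ids,
    )


def save_sequence(out_dir, sequence, write_frames: bool = True) -> None:
    """Write a (synthetic) sequence as the documented directory layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_poses(out / "emt.csv", sequence.emt)
    save_correspondences(out / "correspondences.csv", sequence.correspondences)
    save_intrinsics(out / "intrinsics.json", sequence.intrinsics)
    gt = getattr(sequence, "ground_truth", None)
    if gt is not None:
        save_poses(out / "gt_poses.csv", gt.poses)
        save_plane(out / "gt_plane.json", gt.plane)
        save_homographies(out / "gt_homographies.csv", gt.gt_homographies)
    if write_frames and sequence.frames is not None:
        fdir = out / "frames"
        fdir.mkdir(exist_ok=True)
        for k, img in enumerate(sequence.frames):
            iio.imwrite(fdir / f"frame_{k:05d}.png", img)


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------

_KNOWN_CONFIG_KEYS = {
    "n_frames", "kind", "laps", "radius_mm", "frame_size", "seed",
    "nu", "sigma_v", "n_points", "render", "blank_indices",
    "window", "n_estimate", "n_anchor_clusters", "anchor_run_length",
    "sigma_emt_rot_deg", "sigma_emt_trans_mm", "sigma_p_rot_deg",
    "sigma_p_trans_mm", "plane_distance_mm", "freeze_plane",
    "recompose_at_end", "n_grid", "nu_values", "indices",
}


def load_run_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown keys."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"cannot parse YAML config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"config {path} must be a mapping")
    unknown = sorted(set(data) - _KNOWN_CONFIG_KEYS)
    if unknown:
        raise SchemaError(f"unknown config keys in {path}: {unknown}")
    return data


def write_manifest(out_dir, config: dict, seed=None) -> None:
    from . import __version__

    blob = yaml.safe_dump(config, sort_keys=True)
    manifest = {
        "package": "emtmosaic",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(out_dir, "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
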