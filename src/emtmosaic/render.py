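"""Mosaic rendering: canvas bounds, inverse warping and feathered blending."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .errors import CanvasOverflowError
from .geometry import Homography, apply_homography

__all__ = ["MosaicCanvas", "compute_canvas", "warp_blend"]


@dataclass
class MosaicCanvas:
    """Accumulated mosaic: bounds in mosaic space, blended image, blend weights."""

    bounds: tuple  # (xmin, ymin, xmax, ymax), px, mosaic space
    image: np.ndarray  # uint8 RGB
    weight: np.ndarray  # per-pixel accumulated blend weight

    @property
    def shape(self):
        return self.image.shape


def compute_canvas(homographies, frame_size, pad: int = 2,
                   max_area: float = 1e8) -> tuple:
    """Axis-aligned bounds of all frame footprints in mosaic space.

    Raises :class:`CanvasOverflowError` when the bounded area exceeds
    ``max_area`` pixels — typically a symptom of drift blowing up the
    projections.
    """
    if len(homographies) == 0:
        raise ValueError("compute_canvas requires at least one homography")
    w, h = frame_size
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    pts = np.concatenate([
        apply_homography(np.linalg.inv(H.H if isinstance(H, Homography) else H), corners)
        for H in homographies
    ])
    xmin, ymin = np.floor(pts.min(axis=0)) - pad
    xmax, ymax = np.ceil(pts.max(axis=0)) + pad
    area = (xmax - xmin + 1) * (ymax - ymin + 1)
    if area > max_area:
        raise CanvasOverflowError(
            f"canvas area {area:.3g} px exceeds cap {max_area:.3g} px")
    return (int(xmin), int(ymin), int(xmax), int(ymax))


def _feather_weight(frame_size, fov_radius=None) -> np.ndarray:
    """Distance-to-edge feathering, optionally masked to a circular field of view."""
    w, h = frame_size
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    wx = np.minimum(xs + 1.0, w - xs)
    wy = np.minimum(ys + 1.0, h - ys)
    wgt = np.minimum(wy[:, None], wx[None, :])
    wgt /= wgt.max()
    if fov_radius is not None:
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        rr = np.hypot(np.arange(w)[None, :] - cx, np.arange(h)[:, None] - cy)
        wgt = wgt * (rr <= fov_radius)
    return wgt


def warp_blend(frames, homographies, border: bool = False, canvas=None,
               fov_radius=None, pad: int = 2, max_area: float = 1e8) -> MosaicCanvas:
    """Inverse-warp every frame through ``H_j^{-1}`` and blend linearly.

    Blend weight is the feathered distance to the frame edge, so the output
    at every rendered pixel is a convex combination of the contributing
    frames.  ``border=True`` stamps a thin (2 px) black ring at each frame's
    circular field-of-view boundary, in stitching order, to visualize seams;
    the ring radius defaults to ``min(w, h) / 2``.
    """
    if len(frames) != len(homographies):
        raise ValueError("frames and homographies must have equal length")
    h, w = np.asarray(frames[0]).shape[:2]
    frame_size = (w, h)
    if canvas is None:
        canvas = compute_canvas(homographies, frame_size, pad, max_area)
    xmin, ymin, xmax, ymax = canvas
    out_shape = (ymax - ymin + 1, xmax - xmin + 1)
    T = np.eye(3)
    T[:2, 2] = (xmin, ymin)

    acc = np.zeros((*out_shape, 3))
    wacc = np.zeros(out_shape)
    feather = _feather_weight(frame_size, fov_radius)
    ring_radius = (min(w, h) / 2.0) if fov_radius is None else fov_radius
    ring_masks = []
    for frame, H in zip(frames, homographies):
        M = (H.H if isinstance(H, Homography) else np.asarray(H)) @ T
        tform = ProjectiveTransform(matrix=M)
        img = warp(np.asarray(frame).astype(float), tform, output_shape=out_shape,
                   order=1, preserve_range=True, cval=0.0)
        if img.ndim == 2:
            img = img[..., None].repeat(3, axis=-1)
        wgt = warp(feather, tform, output_shape=out_shape, order=1, cval=0.0)
        acc += img * wgt[..., None]
        wacc += wgt
        if border:
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            rr = np.hypot(np.arange(w)[None, :] - cx, np.arange(h)[:, None] - cy)
            ring = (np.abs(rr - ring_radius) <= 1.0).astype(float)
            ring_masks.append(warp(ring, tform, output_shape=out_shape, order=0))

    rendered = wacc > 1e-12
    img_out = np.zeros((*out_shape, 3))
    img_out[rendered] = acc[rendered] / wacc[rendered, None]
    for ring in ring_masks:  # stamp seams in stitching order
        img_out[ring > 0.5] = 0.0
    return MosaicCanvas(
        bounds=canvas,
        image=np.clip(np.round(img_out), 0, 255).astype(np.uint8),
        weight=wacc,
    )
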