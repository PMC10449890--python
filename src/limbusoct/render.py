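"""Depth-encoded rendering, flattening, en-face and axis projections.

Depth encoding paints each tissue pixel by its depth below the segmented
anterior surface using the HSV model: hue runs from 0 (red, at the
surface) to 2/3 (blue, at or beyond the depth ceiling) so a rainbow
red-yellow-green-blue gradation tracks depth, saturation is 1, and value
carries the image intensity.  Pixels above the surface are black.

Flattening shifts each column so the segmented surface sits at row 0;
en-face views are then minimum projections over a slab of constant
depth-below-surface (the low-backscatter lumen of Schlemm's canal appears
as a dark trough).  Vacated rows are zero-filled, and exact zeros are
treated as missing when taking slab minima so the fill cannot masquerade
as tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

__all__ = [
    "DepthEncodedImage",
    "FlattenedVolume",
    "HUE_CEILING",
    "DEFAULT_SLAB_ROWS",
    "mask_above_surface",
    "depth_hue",
    "depth_encode",
    "flatten_volume",
    "unflatten_volume",
    "enface_min_projection",
    "intensity_projection",
    "concat_panorama",
]

#: hue assigned at/beyond the depth ceiling (blue); 0 is red at the surface
HUE_CEILING = 2.0 / 3.0
#: default en-face slab (rows below the flattened surface)
DEFAULT_SLAB_ROWS = (286, 320)

PROJECTION_KINDS = ("max", "min", "mean", "median", "sum", "std")


@dataclass
class DepthEncodedImage:
    """RGB rendering of one frame with depth coded into hue."""

    rgb: np.ndarray  # (rows, cols, 3) in [0, 1]
    boundary_rows: np.ndarray
    depth_scale_um: float

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.rgb * 255), 0, 255).astype(np.uint8)


@dataclass
class FlattenedVolume:
    """Volume with each column shifted so the surface sits at row 0."""

    data: np.ndarray  # (frames, rows, cols)
    shifts: np.ndarray  # (frames, cols) integer upward shift applied

    def unflatten(self) -> np.ndarray:
        """Invert the per-column shifts (exact to the integer rounding)."""
        return unflatten_volume(self)


def _boundary_rows(boundary, n_cols: int) -> np.ndarray:
    rows = boundary.rows if hasattr(boundary, "rows") else np.asarray(boundary)
    rows = np.asarray(rows, dtype=float)
    if rows.size != n_cols:
        raise ValueError("boundary width does not match the image")
    return rows


def mask_above_surface(image: np.ndarray, boundary) -> np.ndarray:
    """Blacken everything above the surface boundary (rows < boundary)."""
    image = np.asarray(image)
    rows = _boundary_rows(boundary, image.shape[1])
    r = np.arange(image.shape[0])[:, None]
    out = image.copy()
    out[r < rows[None, :]] = 0
    return out


def depth_hue(depth_um, depth_scale_um: float):
    """Hue of a tissue pixel ``depth_um`` below the surface.

    H = (2/3) * min(d / Dmax, 1): exactly 0 at the surface and exactly 2/3
    at or beyond the ceiling, monotone non-decreasing in between.
    """
    if depth_scale_um <= 0:
        raise ValueError("depth scale must be positive")
    d = np.asarray(depth_um, dtype=float)
    return HUE_CEILING * np.minimum(d / depth_scale_um, 1.0)


def depth_encode(
    image: np.ndarray,
    boundary,
    depth_scale_um: float | None = None,
    pitch_um: float = 2.0,
) -> DepthEncodedImage:
    """HSV depth encoding of one frame.

    Hue = depth below the segmented surface mapped onto [0, 2/3],
    saturation = 1, value = image intensity (expected in [0, 1]); pixels
    above the surface are exactly black.  ``depth_scale_um`` defaults to
    the full below-surface depth of the frame.
    """
    image = np.asarray(image, dtype=float)
    n_rows, n_cols = image.shape
    rows = _boundary_rows(boundary, n_cols)
    if depth_scale_um is None:
        depth_scale_um = float((n_rows - 1 - rows.min()) * pitch_um)
    if depth_scale_um <= 0:
        raise ValueError("depth scale must be positive")

    r = np.arange(n_rows)[:, None]
    depth_um = (r - rows[None, :]) * pitch_um
    tissue = depth_um >= 0

    hsv = np.zeros((n_rows, n_cols, 3))
    hsv[..., 0] = depth_hue(np.maximum(depth_um, 0.0), depth_scale_um)
    hsv[..., 1] = 1.0
    hsv[..., 2] = np.clip(image, 0.0, 1.0)
    rgb = hsv_to_rgb(hsv)
    rgb[~tissue] = 0.0
    return DepthEncodedImage(rgb=rgb, boundary_rows=rows, depth_scale_um=depth_scale_um)


def flatten_volume(volume: np.ndarray, boundaries) -> FlattenedVolume:
    """Shift every column up by its (rounded) boundary row.

    After flattening the surface sits at row 0 in every column; vacated
    bottom rows are zero-filled.  The shift table supports inversion to
    within the one-row rounding.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be (frames, rows, cols)")
    n_frames, n_rows, n_cols = volume.shape
    if len(boundaries) != n_frames:
        raise ValueError("need one boundary per frame")
    shifts = np.zeros((n_frames, n_cols), dtype=int)
    out = np.zeros_like(volume)
    for f in range(n_frames):
        rows = _boundary_rows(boundaries[f], n_cols)
        s = np.clip(np.rint(rows).astype(int), 0, n_rows - 1)
        shifts[f] = s
        for c in range(n_cols):
            out[f, : n_rows - s[c], c] = volume[f, s[c]:, c]
    return FlattenedVolume(data=out, shifts=shifts)


def unflatten_volume(flat: FlattenedVolume) -> np.ndarray:
    """Restore the original geometry from a flattened volume."""
    n_frames, n_rows, n_cols = flat.data.shape
    out = np.zeros_like(flat.data)
    for f in range(n_frames):
        for c in range(n_cols):
            s = flat.shifts[f, c]
            out[f, s:, c] = flat.data[f, : n_rows - s, c]
    return out


def enface_min_projection(flat: FlattenedVolume, row_range=DEFAULT_SLAB_ROWS) -> np.ndarray:
    """Minimum projection over a slab of the flattened volume.

    ``row_range`` = inclusive (r1, r2) rows below the flattened surface
    (defaults to rows 286-320).  Exact-zero fill values are treated as
    missing; a pixel whose slab is entirely fill projects to 0.  Output
    shape is (frames, cols): one en-face value per (y, x).
    """
    r1, r2 = row_range
    n_rows = flat.data.shape[1]
    if not (0 <= r1 <= r2 < n_rows):
        raise ValueError(f"slab rows ({r1}, {r2}) outside the volume depth {n_rows}")
    slab = flat.data[:, r1 : r2 + 1, :]
    masked = np.ma.masked_equal(slab, 0.0)
    out = masked.min(axis=1)
    return np.ma.filled(out, 0.0)


def intensity_projection(volume: np.ndarray, axis=0, kind: str = "max") -> np.ndarray:
    """Axis projection of a volume by one of max, min, mean, median, sum,
    std (population convention)."""
    volume = np.asarray(volume)
    if kind not in PROJECTION_KINDS:
        raise ValueError(f"unknown projection kind {kind!r}; use one of {PROJECTION_KINDS}")
    if not 0 <= (axis if axis >= 0 else volume.ndim + axis) < volume.ndim:
        raise ValueError(f"invalid axis {axis} for volume of ndim {volume.ndim}")
    fn = {
        "max": np.max,
        "min": np.min,
        "mean": np.mean,
        "median": np.median,
        "sum": np.sum,
        "std": np.std,
    }[kind]
    return fn(volume, axis=axis)


def concat_panorama(frames, overlap: int = 0) -> np.ndarray:
    """Side-by-side concatenation of circumferential frames.

    Consecutive frames share ``overlap`` columns, which are cropped from
    the left edge of every frame after the first; the panorama width is the
    sum of widths minus the overlaps.
    """
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("no frames to concatenate")
    h = frames[0].shape[0]
    if any(f.shape[0] != h for f in frames):
        raise ValueError("frame heights differ")
    if overlap < 0 or any(overlap >= f.shape[1] for f in frames[1:]):
        raise ValueError("overlap must be non-negative and smaller than a frame")
    parts = [frames[0]] + [f[:, overlap:] for f in frames[1:]]
    return np.concatenate(parts, axis=1)
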