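"""Physical scaling and conditioning of reconstructed B-scans.

Converts a reconstructed log-intensity frame into the isometric, filtered,
[0,1]-normalized image the segmentation stage expects: air-to-tissue depth
scaling with a single averaged refractive index (1.336 for cornea, sclera
and aqueous humor), bilinear resampling to square 2 µm pixels, a 3x3 median
filter, and an affine rescale to [0,1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, zoom

from .recon import BScanImage

__all__ = [
    "IsometricImage",
    "scale_depth_refractive",
    "resample_isometric",
    "crop_rows",
    "median_filter_3x3",
    "rescale01",
    "postprocess_bscan",
]

DEFAULT_TISSUE_INDEX = 1.336
DEFAULT_PITCH_UM = 2.0
DEFAULT_CROP_ROWS = 798


@dataclass
class IsometricImage:
    """Intensity image on square pixels with physical pitch metadata."""

    data: np.ndarray
    pitch_um: float
    tissue_index: float = DEFAULT_TISSUE_INDEX

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")


def scale_depth_refractive(image: BScanImage, n: float = DEFAULT_TISSUE_INDEX) -> BScanImage:
    """Convert the optical depth axis to physical depth: pitch -> pitch / n.

    A single averaged tissue index is applied to the whole axis (no
    per-layer correction), so this is a pure metadata operation.
    """
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    return BScanImage(
        data=image.data,
        axial_pitch_um=image.axial_pitch_um / n,
        lateral_pitch_um=image.lateral_pitch_um,
        dc_at_bottom=image.dc_at_bottom,
        provenance=image.provenance + [f"scale_depth_refractive(n={n})"],
    )


def resample_isometric(
    image: BScanImage, target_pitch_um: float = DEFAULT_PITCH_UM
) -> BScanImage:
    """Bilinear resampling to square pixels of ``target_pitch_um``.

    Physical extents are preserved to within one target pixel.  A frame
    already isometric at the target pitch passes through unchanged.
    """
    if target_pitch_um <= 0:
        raise ValueError("target pitch must be positive")
    fr = image.axial_pitch_um / target_pitch_um
    fc = image.lateral_pitch_um / target_pitch_um
    if abs(fr - 1) < 1e-9 and abs(fc - 1) < 1e-9:
        out = image.data
    else:
        out = zoom(image.data, (fr, fc), order=1, grid_mode=True, mode="nearest")
    return BScanImage(
        data=out,
        axial_pitch_um=target_pitch_um,
        lateral_pitch_um=target_pitch_um,
        dc_at_bottom=image.dc_at_bottom,
        provenance=image.provenance + [f"resample_isometric({target_pitch_um})"],
    )


def crop_rows(image: BScanImage, n_rows: int = DEFAULT_CROP_ROWS) -> BScanImage:
    """Keep the ``n_rows`` rows adjacent to DC (the bottom of the frame).

    With the sample positioned across the zero delay, the surface and all
    tissue sit in the rows nearest DC, so this retains the surface side and
    discards the empty extended-depth region at the top.
    """
    if n_rows < 1:
        raise ValueError("need at least one row")
    n_rows = min(n_rows, image.data.shape[0])
    return BScanImage(
        data=image.data[-n_rows:],
        axial_pitch_um=image.axial_pitch_um,
        lateral_pitch_um=image.lateral_pitch_um,
        dc_at_bottom=image.dc_at_bottom,
        provenance=image.provenance + [f"crop_rows({n_rows})"],
    )


def median_filter_3x3(image):
    """3x3 median filter with reflective boundary handling."""
    data = image.data if isinstance(image, BScanImage) else np.asarray(image)
    out = median_filter(data, size=3, mode="reflect")
    if isinstance(image, BScanImage):
        return BScanImage(
            data=out,
            axial_pitch_um=image.axial_pitch_um,
            lateral_pitch_um=image.lateral_pitch_um,
            dc_at_bottom=image.dc_at_bottom,
            provenance=image.provenance + ["median_filter_3x3"],
        )
    return out


def rescale01(image):
    """Affine map of the intensity range onto [0, 1] exactly.

    A constant image has no range; it maps to all zeros with a warning.
    """
    data = image.data if isinstance(image, BScanImage) else np.asarray(image)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        warnings.warn("constant image: rescale01 returns all zeros")
        out = np.zeros_like(data, dtype=float)
    else:
        out = (data - lo) / (hi - lo)
    if isinstance(image, BScanImage):
        return BScanImage(
            data=out,
            axial_pitch_um=image.axial_pitch_um,
            lateral_pitch_um=image.lateral_pitch_um,
            dc_at_bottom=image.dc_at_bottom,
            provenance=image.provenance + ["rescale01"],
        )
    return out


def postprocess_bscan(
    image: BScanImage,
    tissue_index: float = DEFAULT_TISSUE_INDEX,
    target_pitch_um: float = DEFAULT_PITCH_UM,
    n_rows: int = DEFAULT_CROP_ROWS,
) -> IsometricImage:
    """Full conditioning chain: refractive scaling -> isometric resampling
    -> row crop -> 3x3 median -> rescale to [0,1]."""
    img = scale_depth_refractive(image, tissue_index)
    img = resample_isometric(img, target_pitch_um)
    img = crop_rows(img, n_rows)
    img = median_filter_3x3(img)
    img = rescale01(img)
    return IsometricImage(
        data=np.asarray(img.data, dtype=np.float32),
        pitch_um=target_pitch_um,
        tissue_index=tissue_index,
    )
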