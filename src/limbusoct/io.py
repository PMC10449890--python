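"""Multi-page TIFF volume I/O with JSON sidecars.

Volumes travel as multi-page TIFF (one page per frame): grayscale 16-bit
for intensity stacks, 8-bit RGB for depth-encoded renderings, float32 for
raw spectral frames.  Physical pitches, calibration references, seeds and
processing provenance ride in a JSON sidecar next to the TIFF
(``<name>.json``).  Integer data round-trips bit-identically.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "sidecar_path",
    "write_stack",
    "read_stack",
    "iter_frames",
    "quantize16",
    "dequantize16",
]


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_stack(volume: np.ndarray, path, metadata: dict | None = None) -> Path:
    """Write a (frames, rows, cols[, 3]) volume as multi-page TIFF plus a
    JSON sidecar with the metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    volume = np.asarray(volume)
    tifffile.imwrite(path, volume, photometric="rgb" if volume.ndim == 4 else "minisblack")
    meta = dict(metadata or {})
    meta.setdefault("dtype", str(volume.dtype))
    meta.setdefault("shape", list(volume.shape))
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_stack(path):
    """Read a multi-page TIFF volume and its sidecar metadata.

    A missing sidecar yields empty metadata with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    volume = tifffile.imread(path)
    sp = sidecar_path(path)
    if sp.exists():
        metadata = json.loads(sp.read_text())
    else:
        warnings.warn(f"no sidecar for {path.name}; using defaults")
        metadata = {}
    return volume, metadata


def iter_frames(path):
    """Yield frames of a multi-page TIFF one page at a time.

    Pages are decoded lazily, so a long stack can be scanned without
    holding the whole volume in memory.
    """
    with tifffile.TiffFile(Path(path)) as tif:
        for page in tif.pages:
            yield page.asarray()


def quantize16(volume: np.ndarray, lo: float | None = None, hi: float | None = None):
    """Map a float volume onto uint16 for storage; returns (u16, lo, hi)."""
    volume = np.asarray(volume, dtype=float)
    lo = float(volume.min()) if lo is None else lo
    hi = float(volume.max()) if hi is None else hi
    if hi <= lo:
        return np.zeros(volume.shape, dtype=np.uint16), lo, hi
    scaled = (volume - lo) / (hi - lo)
    return np.clip(np.rint(scaled * 65535), 0, 65535).astype(np.uint16), lo, hi


def dequantize16(u16: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * (np.asarray(u16, dtype=float) / 65535.0)
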