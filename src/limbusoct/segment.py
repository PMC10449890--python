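"""Semi-automatic anterior-surface segmentation.

The anterior corneal/conjunctival surface is segmented frame by frame: a
handful of manual seed points on the first frame are interpolated and
refined by a banded shortest-path search on a gradient cost image, the raw
path is smoothed by a degree-9 polynomial fit, and the fitted boundary of
each frame seeds a +/-20 µm search band for the next frame (frames are only
10 µm apart, so the surface moves little between them).

The shortest path is computed exactly by dynamic programming over
left-to-right connected paths whose vertical step between adjacent columns
is limited to +/-2 rows; ties are broken toward the shallower row, since
the anterior surface is the first interface the beam meets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "SurfaceBoundary",
    "SearchBand",
    "gradient_cost_image",
    "shortest_path_boundary",
    "fit_polynomial",
    "segment_first_frame",
    "propagate_stack",
    "boundaries_to_frame",
]

DEFAULT_STEP = 2
DEFAULT_DEGREE = 9
DEFAULT_BAND_UM = 20.0


@dataclass
class SurfaceBoundary:
    """Per-column anterior-surface rows for one frame (sub-pixel)."""

    rows: np.ndarray
    frame_id: int = 0
    pitch_um: float = 2.0
    degree: int = DEFAULT_DEGREE
    coefficients: np.ndarray | None = None
    raw_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 1:
            raise ValueError("boundary must be one row per column")

    @property
    def rows_um(self) -> np.ndarray:
        return self.rows * self.pitch_um

    def __len__(self) -> int:
        return self.rows.size


@dataclass
class SearchBand:
    """A +/- half-width band around a reference boundary (µm units)."""

    reference: SurfaceBoundary
    half_width_um: float = DEFAULT_BAND_UM

    def __post_init__(self) -> None:
        if self.half_width_um <= 0:
            raise ValueError("band half-width must be positive")

    def limits(self, n_rows: int):
        """Inclusive (lo, hi) row limits per column, clipped to the image."""
        half_px = self.half_width_um / self.reference.pitch_um
        lo = np.clip(np.floor(self.reference.rows - half_px), 0, n_rows - 1)
        hi = np.clip(np.ceil(self.reference.rows + half_px), 0, n_rows - 1)
        return lo.astype(int), hi.astype(int)


def gradient_cost_image(image: np.ndarray) -> np.ndarray:
    """Cost = 1 - normalized positive vertical gradient, in [0, 1].

    Dark-above/bright-below transitions (air over tissue) are cheap; a
    constant image gives uniform cost 1.
    """
    image = np.asarray(image, dtype=float)
    g = np.gradient(image, axis=0)
    g = np.maximum(g, 0.0)
    m = g.max()
    if m > 0:
        g = g / m
    return 1.0 - g


def shortest_path_boundary(
    cost: np.ndarray,
    band: SearchBand | None = None,
    step: int = DEFAULT_STEP,
) -> np.ndarray:
    """Exact minimum-cost connected left-to-right path through ``cost``.

    The path visits one row per column; the row change between adjacent
    columns is limited to ``+/-step``.  With a band, rows outside the band
    are excluded.  Ties are broken toward the shallower (smaller) row.
    Returns integer rows per column.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost must be 2D")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost must be finite")
    n_rows, n_cols = cost.shape

    if band is not None:
        lo, hi = band.limits(n_rows)
        if np.any(lo > hi):
            bad = int(np.argmax(lo > hi))
            raise ValueError(f"search band empty in column {bad}")
        # a band that separates adjacent columns by more than the step
        # constraint admits no connected path
        if np.any(lo[1:] > hi[:-1] + step) or np.any(hi[1:] < lo[:-1] - step):
            raise ValueError(
                "search band narrower than the step constraint allows; "
                "no connected path exists"
            )
    else:
        lo = np.zeros(n_cols, dtype=int)
        hi = np.full(n_cols, n_rows - 1, dtype=int)

    big = np.inf
    acc = np.where(
        (np.arange(n_rows) >= lo[0]) & (np.arange(n_rows) <= hi[0]),
        cost[:, 0],
        big,
    )
    # predecessor offset per (column, row); offsets scanned shallow-first
    pred = np.zeros((n_cols, n_rows), dtype=np.int8)
    offsets = np.arange(-step, step + 1)
    rows_idx = np.arange(n_rows)
    for c in range(1, n_cols):
        # stack acc shifted by each allowed offset; previous row = row + off
        cand = np.full((offsets.size, n_rows), big)
        for i, off in enumerate(offsets):
            src = rows_idx + off
            ok = (src >= 0) & (src < n_rows)
            cand[i, ok] = acc[src[ok]]
        # shallow-first tie-break: scan offsets in order of previous row
        order = np.argsort(offsets)  # offsets ascending = prev rows ascending
        cand = cand[order]
        best = np.argmin(cand, axis=0)  # first (shallowest prev) minimum
        new_acc = cand[best, rows_idx] + cost[:, c]
        outside = (rows_idx < lo[c]) | (rows_idx > hi[c])
        new_acc[outside] = big
        pred[c] = offsets[order][best]
        acc = new_acc

    if not np.isfinite(acc.min()):
        raise ValueError("no connected path through the band")
    path = np.empty(n_cols, dtype=int)
    path[-1] = int(np.argmin(acc))  # argmin: shallowest among ties
    for c in range(n_cols - 1, 0, -1):
        path[c - 1] = path[c] + pred[c, path[c]]
    return path


def path_cost(cost: np.ndarray, path: np.ndarray) -> float:
    return float(cost[np.asarray(path), np.arange(len(path))].sum())


def fit_polynomial(
    path: np.ndarray,
    degree: int = DEFAULT_DEGREE,
    n_rows: int | None = None,
    frame_id: int = 0,
    pitch_um: float = 2.0,
) -> SurfaceBoundary:
    """Least-squares polynomial smoothing of a raw boundary path.

    Fits over the column index; the fitted values, clipped to the image,
    become the boundary.  Raises if the fit is under-determined.
    """
    path = np.asarray(path, dtype=float)
    if path.size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} columns for a degree-{degree} fit"
        )
    x = np.arange(path.size)
    poly = np.polynomial.Polynomial.fit(x, path, degree)
    fitted = poly(x)
    if n_rows is not None:
        fitted = np.clip(fitted, 0, n_rows - 1)
    return SurfaceBoundary(
        rows=fitted,
        frame_id=frame_id,
        pitch_um=pitch_um,
        degree=degree,
        coefficients=poly.convert().coef,
        raw_rows=path.copy(),
    )


def segment_first_frame(
    image: np.ndarray,
    seeds,
    band_um: float = DEFAULT_BAND_UM,
    degree: int = DEFAULT_DEGREE,
    step: int = DEFAULT_STEP,
    pitch_um: float = 2.0,
) -> SurfaceBoundary:
    """Segment frame 0 from manual seed points.

    ``seeds`` is a sequence of (column, row) points; at least two are
    required and they must span at least half the image width.  Seeds are
    interpolated to a full-width estimate with a monotone cubic (PCHIP),
    refined by one banded shortest-path pass around the estimate, and
    polynomial-smoothed.
    """
    image = np.asarray(image, dtype=float)
    n_rows, n_cols = image.shape
    seeds = np.asarray(seeds, dtype=float)
    if seeds.ndim != 2 or seeds.shape[1] != 2 or seeds.shape[0] < 2:
        raise ValueError("need at least two (column, row) seed points")
    if np.any(seeds[:, 0] < 0) or np.any(seeds[:, 0] > n_cols - 1):
        raise ValueError("seed columns outside the image")
    if np.any(seeds[:, 1] < 0) or np.any(seeds[:, 1] > n_rows - 1):
        raise ValueError("seed rows outside the image")
    order = np.argsort(seeds[:, 0])
    sc, sr = seeds[order, 0], seeds[order, 1]
    if sc[-1] - sc[0] < 0.5 * (n_cols - 1):
        raise ValueError("seeds must span at least half the image width")
    interp = PchipInterpolator(sc, sr, extrapolate=True)
    estimate = np.clip(interp(np.arange(n_cols)), 0, n_rows - 1)

    ref = SurfaceBoundary(estimate, frame_id=0, pitch_um=pitch_um)
    cost = gradient_cost_image(image)
    path = shortest_path_boundary(cost, SearchBand(ref, band_um), step=step)
    return fit_polynomial(
        path, degree=degree, n_rows=n_rows, frame_id=0, pitch_um=pitch_um
    )


def propagate_stack(
    stack: np.ndarray,
    first_boundary: SurfaceBoundary,
    band_um: float = DEFAULT_BAND_UM,
    degree: int = DEFAULT_DEGREE,
    step: int = DEFAULT_STEP,
) -> list[SurfaceBoundary]:
    """Propagate the first frame's boundary through the whole stack.

    For every subsequent frame the previous frame's *fitted* boundary
    defines a +/- ``band_um`` search band; the banded shortest path is
    fitted with the smoothing polynomial and becomes the next reference.
    Fully deterministic.  If a frame's raw path presses against the band
    edge over a substantial run of columns, the surface has likely moved
    farther than the band allows and a divergence warning is issued.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    n_frames, n_rows, n_cols = stack.shape
    if len(first_boundary) != n_cols:
        raise ValueError("first boundary width does not match the stack")
    pitch = first_boundary.pitch_um
    boundaries = [first_boundary]
    prev = first_boundary
    for f in range(1, n_frames):
        band = SearchBand(prev, band_um)
        cost = gradient_cost_image(stack[f])
        try:
            path = shortest_path_boundary(cost, band, step=step)
        except ValueError as exc:
            raise ValueError(f"frame {f}: {exc}") from exc
        lo, hi = band.limits(n_rows)
        clamped = np.mean((path <= lo) | (path >= hi))
        if clamped > 0.25:
            warnings.warn(
                f"frame {f}: boundary clamps to the search-band edge over "
                f"{clamped:.0%} of columns; surface may have moved beyond "
                f"the {band_um} um band",
                stacklevel=2,
            )
        fitted = fit_polynomial(
            path, degree=degree, n_rows=n_rows, frame_id=f, pitch_um=pitch
        )
        boundaries.append(fitted)
        prev = fitted
    return boundaries


def boundaries_to_frame(boundaries) -> pd.DataFrame:
    """Long-format table (frame, column, row_px, row_um) of a boundary list."""
    recs = []
    for b in boundaries:
        recs.append(
            pd.DataFrame(
                {
                    "frame": b.frame_id,
                    "column": np.arange(len(b)),
                    "row_px": b.rows,
                    "row_um": b.rows_um,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)
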