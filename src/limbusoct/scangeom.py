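"""Crossline ("bowtie") scan trajectories and volume-acquisition planning.

The imaging system alternates a radial B-scan line with a circumferential
one: while the radial galvanometer sweeps, the circumferential drive is held
at zero and vice versa, and the beam crosses between the two lines along the
hypotenuses of a bowtie-shaped track.  Slow circumferential coverage is
obtained by translating the eye under the fixed crossline pattern, so each
radial frame sits at a constant circumferential offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CrosslineWaveform",
    "VolumeScanPlan",
    "make_bowtie_waveform",
    "angular_coverage",
    "plan_volume",
]

#: fraction of one scan segment spent on each hypotenuse transition
TRANSITION_FRACTION = 0.1

RADIAL = "radial"
CIRCUMFERENTIAL = "circumferential"
TRANSITION = "transition"


@dataclass
class CrosslineWaveform:
    """Time-stamped 2D beam trajectory with per-sample segment labels.

    Positions are in mm, time in seconds.  Labels are one of ``radial``,
    ``circumferential`` or ``transition``; transition samples are
    non-imaging.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    label: np.ndarray
    aline_rate_hz: float
    radial_length_mm: float
    circ_length_mm: float

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "label": self.label}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def max_step(self) -> float:
        """Largest per-sample displacement (mm); continuity diagnostic."""
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        return float(np.hypot(dx, dy).max()) if dx.size else 0.0


@dataclass
class VolumeScanPlan:
    """Parameters of a stack of radial frames acquired along a translation.

    Defaults give a 1.0 mm-wide radial frame every 10 µm over a 2.5 mm
    circumferential travel (250 frames of 500 A-lines each).
    """

    frame_spacing_um: float = 10.0
    translation_mm: float = 2.5
    frame_width_mm: float = 1.0
    lateral_pitch_um: float = 2.0

    def __post_init__(self) -> None:
        if self.frame_spacing_um <= 0 or self.translation_mm <= 0:
            raise ValueError("spacing and translation must be positive")
        if self.frame_width_mm <= 0 or self.lateral_pitch_um <= 0:
            raise ValueError("frame width and pitch must be positive")
        n = self.translation_mm * 1000.0 / self.frame_spacing_um
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"translation {self.translation_mm} mm is not an integer "
                f"multiple of the {self.frame_spacing_um} um frame spacing"
            )

    @property
    def n_frames(self) -> int:
        return round(self.translation_mm * 1000.0 / self.frame_spacing_um)

    @property
    def alines_per_frame(self) -> int:
        return round(self.frame_width_mm * 1000.0 / self.lateral_pitch_um)


def make_bowtie_waveform(
    radial_length_mm: float = 1.0,
    circ_length_mm: float = 1.0,
    aline_rate_hz: float = 20_000.0,
    lateral_pitch_um: float = 2.0,
    n_periods: int = 1,
) -> CrosslineWaveform:
    """Generate ``n_periods`` of the alternating radial/circumferential scan.

    One period is radial sweep -> hypotenuse transition -> circumferential
    sweep -> hypotenuse back.  During a radial sweep y is held at zero and x
    sweeps linearly across ``radial_length_mm`` (one sample per A-line, i.e.
    one per ``lateral_pitch_um``), and symmetrically for the circumferential
    sweep.  Transitions get 10% of a sweep's sample count and are labelled
    non-imaging.
    """
    if radial_length_mm <= 0 or circ_length_mm <= 0:
        raise ValueError("scan segment lengths must be positive")
    if aline_rate_hz <= 0 or lateral_pitch_um <= 0:
        raise ValueError("rate and pitch must be positive")
    if n_periods < 1:
        raise ValueError("need at least one period")

    n_rad = round(radial_length_mm * 1000.0 / lateral_pitch_um)
    n_cir = round(circ_length_mm * 1000.0 / lateral_pitch_um)
    if n_rad < 2 or n_cir < 2:
        raise ValueError("scan segments too short for the requested pitch")
    n_tr = max(2, round(TRANSITION_FRACTION * n_rad))

    hx = radial_length_mm / 2.0
    hy = circ_length_mm / 2.0

    # endpoints of each leg; transitions run along the bowtie hypotenuses
    seg_specs = [
        (RADIAL, (-hx, 0.0), (hx, 0.0), n_rad),
        (TRANSITION, (hx, 0.0), (0.0, -hy), n_tr),
        (CIRCUMFERENTIAL, (0.0, -hy), (0.0, hy), n_cir),
        (TRANSITION, (0.0, hy), (-hx, 0.0), n_tr),
    ]

    xs, ys, labels = [], [], []
    for _ in range(n_periods):
        for name, (x0, y0), (x1, y1), n in seg_specs:
            # endpoint=False so the next segment supplies the shared point
            frac = np.arange(n) / n
            xs.append(x0 + (x1 - x0) * frac)
            ys.append(y0 + (y1 - y0) * frac)
            labels.append(np.full(n, name, dtype=object))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    label = np.concatenate(labels)
    t = np.arange(x.size) / aline_rate_hz
    return CrosslineWaveform(
        t=t,
        x=x,
        y=y,
        label=label,
        aline_rate_hz=aline_rate_hz,
        radial_length_mm=radial_length_mm,
        circ_length_mm=circ_length_mm,
    )


def angular_coverage(chord_mm: float, diameter_mm: float) -> float:
    """Angular span (degrees) of a chord of length ``chord_mm`` viewed on a
    ring of diameter ``diameter_mm``: theta = 2*atan(d/D).

    Used to express a circumferential scan length as a fraction of the
    ring-shaped Schlemm's canal (mean spur-to-spur diameter ~11.8 mm).
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    if chord_mm < 0:
        raise ValueError("chord must be non-negative")
    return math.degrees(2.0 * math.atan(chord_mm / diameter_mm))


def plan_volume(plan: VolumeScanPlan | None = None) -> pd.DataFrame:
    """Frame-position table for a translated radial stack.

    Returns one row per frame with the circumferential offset (µm) and the
    first/last A-line x positions (mm); per-frame A-line x positions are the
    same for all frames and can be reconstructed from width and pitch.
    """
    plan = plan or VolumeScanPlan()
    offsets = np.arange(plan.n_frames) * plan.frame_spacing_um
    half = plan.frame_width_mm / 2.0
    return pd.DataFrame(
        {
            "frame": np.arange(plan.n_frames),
            "y_offset_um": offsets,
            "x_start_mm": -half,
            "x_stop_mm": half,
            "n_alines": plan.alines_per_frame,
        }
    )
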