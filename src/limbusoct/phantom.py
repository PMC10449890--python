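"""Parametric limbus phantom and spectral interferogram synthesis.

No public OCT recordings of the iridocorneal angle exist to regress
against, so every downstream stage is exercised on a synthetic scene that
emulates the anatomy of a radially scanned corneoscleral limbus:

* a bright, curved anterior surface (conjunctiva/cornea over sclera),
* a moderately scattering sclera below it,
* a trabecular-meshwork (TM) wedge at depth,
* the low-backscatter lumen of Schlemm's canal (SC) sitting right above
  the TM as a prolate ellipse in cross-section, running circumferentially,
* thin collector channels (CC, ~30 µm calibre) above the SC,
* a dark anterior-chamber (AC) wedge on the cornea side with the iris
  below it,
* an opaque surface defect that casts an axial shadow.

Two rendering routes exist.  The spectral route discretizes the scene into
per-A-line scatterer columns and synthesizes raw interferograms

    I(lambda_i) = B(lambda_i) * (1 + sum_j a_j cos(2 k_i z_j + phi_d(k_i))) + eps_i

so the whole reconstruction chain (k-linearization, dispersion, FFT) is
tested end to end.  The image-domain shortcut rasterizes reflectivity
(with speckle and shadowing) straight into isometric [0,1] B-scans, which
is orders of magnitude faster and is what the segmentation and
visualization tests use.

Scene geometry is expressed in physical micrometres in the frame of the
final processed image (row 0 at the top, 2 µm isometric pixels); the
spectral forward model maps a voxel at depth-from-frame-top t to the
optical path difference z = n * (H - t) with H the frame height, i.e. the
deepest row sits at zero path difference (DC at the bottom of the frame,
surface near the top).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import SpectralFrame

__all__ = [
    "LABELS",
    "SourceSpectrumModel",
    "LimbusPhantom",
    "GroundTruth",
    "ScattererColumn",
    "build_source_spectrum",
    "rasterize_phantom",
    "render_bscan_stack",
    "scatterer_columns",
    "synthesize_interferogram",
]

#: label codes for the rasterized scene
LABELS = {
    "BACKGROUND": 0,
    "SCLERA": 1,
    "TM": 2,
    "SC": 3,
    "CC": 4,
    "IRIS": 5,
    "AC": 6,
    "DEFECT": 7,
}

#: spectrometer sampling window (µm); chosen so a 798-row, 2-µm frame fits
#: below the worst-case local Nyquist depth of uniform-wavelength sampling
DEFAULT_WAVELENGTH_RANGE = (0.780, 0.920)
DEFAULT_N_PIXELS = 2048


@dataclass
class SourceSpectrumModel:
    """Broadband source built from up to three SLDs and two beam combiners.

    ``components`` lists (center wavelength µm, FWHM µm, peak power a.u.).
    The first combiner (``bs1_ratio`` = transmission:reflection fractions)
    merges SLD1 and SLD2; the second (``bs2_ratio``) merges that pair with
    SLD3.  With the default 50:50 and 70:30 ratios and three 100-unit
    SLDs the output component weights are 35:35:30 units.

    Defaults give a combined spectrum with ~850 nm centroid and ~165 nm
    FWHM bandwidth.
    """

    components: list = field(
        default_factory=lambda: [
            (0.7954, 0.060, 100.0),
            (0.8529, 0.060, 100.0),
            (0.9104, 0.060, 100.0),
        ]
    )
    bs1_ratio: tuple = (0.5, 0.5)
    bs2_ratio: tuple = (0.7, 0.3)
    n_pixels: int = DEFAULT_N_PIXELS
    wavelength_range_um: tuple = (0.70, 1.00)

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 3:
            raise ValueError("between one and three SLD components supported")
        for c, fw, p in self.components:
            if c <= 0 or fw <= 0:
                raise ValueError("center and bandwidth must be positive")
            if p < 0:
                raise ValueError("component powers must be non-negative")
        for name, ratio in (("bs1", self.bs1_ratio), ("bs2", self.bs2_ratio)):
            t, r = ratio
            if t < 0 or r < 0 or abs(t + r - 1.0) > 1e-9:
                raise ValueError(
                    f"{name} transmission:reflection fractions must be "
                    f"non-negative and sum to 1, got {ratio}"
                )

    def wavelength_grid(self) -> np.ndarray:
        """Uniform-in-wavelength sampling grid (µm), strictly increasing."""
        lo, hi = self.wavelength_range_um
        return np.linspace(lo, hi, self.n_pixels)

    def component_weights(self) -> np.ndarray:
        """Net splitter attenuation per SLD after both combiners."""
        t1, r1 = self.bs1_ratio
        t2, r2 = self.bs2_ratio
        return np.array([t1 * t2, r1 * t2, r2][: len(self.components)])


def build_source_spectrum(
    model: SourceSpectrumModel,
    wavelength_um: np.ndarray | None = None,
    normalized: bool = False,
) -> np.ndarray:
    """Combined source output spectrum on ``wavelength_um``.

    Each SLD is a Gaussian in wavelength with the given peak power; the
    combined output is the weighted sum with the splitter attenuations from
    :meth:`SourceSpectrumModel.component_weights`.  Nonnegative everywhere.
    """
    lam = model.wavelength_grid() if wavelength_um is None else np.asarray(wavelength_um)
    if lam.ndim != 1 or lam.size < 2 or not np.all(np.diff(lam) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    out = np.zeros_like(lam, dtype=float)
    for (c, fw, p), w in zip(model.components, model.component_weights()):
        out += w * p * np.exp(-4.0 * np.log(2.0) * ((lam - c) / fw) ** 2)
    if normalized and out.max() > 0:
        out = out / out.max()
    return out


@dataclass
class LimbusPhantom:
    """Parametric ground-truth scene of a radially scanned limbus.

    Lateral x spans ``n_cols * pitch_um`` (cornea/AC on the left, sclera on
    the right), depth t spans ``n_rows * pitch_um`` from the frame top, and
    the slow axis y steps circumferentially by ``frame_spacing_um`` per
    frame.  All structure parameters are physical micrometres.
    """

    n_rows: int = 798
    n_cols: int = 500
    n_frames: int = 250
    pitch_um: float = 2.0
    frame_spacing_um: float = 10.0
    tissue_index: float = 1.336

    # anterior surface t_s(x, y): base + sag + tilt + slow drift across y
    surface_base_um: float = 150.0
    surface_sag_um: float = 120.0
    surface_tilt_um: float = 40.0
    surface_drift_um: float = 30.0

    # Schlemm's canal ellipse (cross-section), wobbling slowly along y;
    # centered 606 µm below the surface so the canal sits inside the
    # standard en-face slab (rows 286-320 below the flattened surface)
    sc_center_x_um: float = 520.0
    sc_depth_um: float = 606.0
    sc_semi_x_um: float = 130.0
    sc_semi_z_um: float = 28.0
    sc_wobble_um: float = 25.0

    # TM wedge below the SC
    tm_x_range_um: tuple = (360.0, 680.0)
    tm_top_um: float = 650.0
    tm_thickness_um: tuple = (40.0, 120.0)

    # collector channels: circumferential tubes above the SC
    cc_tubes: tuple = ((585.0, 510.0, 16.0), (445.0, 535.0, 14.0))

    # surface defect (opaque, shadow-casting)
    defect_x_um: float = 790.0
    defect_halfwidth_um: float = 25.0
    defect_depth_um: float = 35.0
    defect_opacity_per_um: float = 0.5

    # mean amplitude reflectivity per tissue class
    reflectivity: dict = field(
        default_factory=lambda: {
            "SCLERA": 0.55,
            "TM": 0.35,
            "SC": 0.06,
            "CC": 0.10,
            "IRIS": 0.40,
            "AC": 0.03,
            "DEFECT": 0.85,
        }
    )
    speckle_sigma: float = 0.35

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        r = self.reflectivity
        if not (r["SC"] < r["TM"] < r["SCLERA"]):
            raise ValueError(
                "reflectivity ordering violated: need SC < TM < sclera"
            )
        if min(self.n_rows, self.n_cols, self.n_frames) < 1:
            raise ValueError("phantom grid must be non-empty")

    @property
    def width_um(self) -> float:
        return self.n_cols * self.pitch_um

    @property
    def height_um(self) -> float:
        return self.n_rows * self.pitch_um

    def surface_um(self, x_um: np.ndarray, frame: int) -> np.ndarray:
        """Anterior-surface depth from the frame top (µm) at lateral x."""
        xc = (np.asarray(x_um, dtype=float) - 0.5 * self.width_um) / (
            0.5 * self.width_um
        )
        yfrac = frame / max(self.n_frames - 1, 1) - 0.5
        return (
            self.surface_base_um
            + self.surface_sag_um * xc**2
            + self.surface_tilt_um * xc
            + self.surface_drift_um * yfrac
        )


@dataclass
class GroundTruth:
    """Rasterized oracle for a phantom: surface rows, labels, shadow mask."""

    surface_rows: np.ndarray  # (n_frames, n_cols) int
    labels: np.ndarray  # (n_frames, n_rows, n_cols) uint8
    shadow: np.ndarray  # same shape, bool
    pitch_um: float

    def label_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


def _rasterize_frame(phantom: LimbusPhantom, frame: int):
    p = phantom
    x = (np.arange(p.n_cols) + 0.5) * p.pitch_um
    t = (np.arange(p.n_rows) + 0.5) * p.pitch_um
    X, T = np.meshgrid(x, t)  # (n_rows, n_cols)

    surf = p.surface_um(x, frame)
    if np.any(surf < 0) or np.any(surf > p.height_um - p.pitch_um):
        raise ValueError("surface leaves the phantom frame")
    d = T - surf[None, :]  # depth below the local surface
    below = d >= 0

    labels = np.zeros((p.n_rows, p.n_cols), dtype=np.uint8)
    labels[below] = LABELS["SCLERA"]

    # anterior chamber wedge on the cornea side, iris underneath
    ac_top = 260.0 + 0.55 * X
    ac = below & (X < 360.0) & (d > ac_top)
    labels[ac] = LABELS["AC"]
    iris = below & (X < 300.0) & (d > ac_top + 420.0)
    labels[iris] = LABELS["IRIS"]

    # TM wedge (thickens toward the sclera side)
    x0, x1 = p.tm_x_range_um
    th0, th1 = p.tm_thickness_um
    frac = np.clip((X - x0) / max(x1 - x0, 1e-9), 0.0, 1.0)
    tm = (
        below
        & (X >= x0)
        & (X <= x1)
        & (d >= p.tm_top_um)
        & (d <= p.tm_top_um + th0 + (th1 - th0) * frac)
    )
    labels[tm] = LABELS["TM"]

    # SC lumen: prolate ellipse right above the TM, wobbling along y
    yfrac = frame / max(p.n_frames - 1, 1)
    xc = p.sc_center_x_um + p.sc_wobble_um * np.sin(2.0 * np.pi * yfrac)
    sc = below & (
        ((X - xc) / p.sc_semi_x_um) ** 2 + ((d - p.sc_depth_um) / p.sc_semi_z_um) ** 2
        <= 1.0
    )
    labels[sc] = LABELS["SC"]

    # collector channels: tubes running along y, plus a branch from the SC
    for cx, cd, cr in p.cc_tubes:
        cc = below & (((X - cx) ** 2 + (d - cd) ** 2) <= cr**2)
        labels[cc] = LABELS["CC"]
    if 0.33 <= yfrac <= 0.67:
        # slanted branch from the SC roof to the first tube
        bx0, bd0 = xc, p.sc_depth_um - p.sc_semi_z_um
        bx1, bd1, _ = p.cc_tubes[0]
        u = np.clip(
            ((X - bx0) * (bx1 - bx0) + (d - bd0) * (bd1 - bd0))
            / ((bx1 - bx0) ** 2 + (bd1 - bd0) ** 2),
            0.0,
            1.0,
        )
        dist2 = (X - (bx0 + u * (bx1 - bx0))) ** 2 + (d - (bd0 + u * (bd1 - bd0))) ** 2
        labels[below & (dist2 <= 12.0**2)] = LABELS["CC"]

    # opaque surface defect
    defect = (
        below
        & (np.abs(X - p.defect_x_um) <= p.defect_halfwidth_um)
        & (d <= p.defect_depth_um)
    )
    labels[defect] = LABELS["DEFECT"]

    # shadow: everything axially below a defect voxel in the same column
    shadow = np.zeros_like(defect)
    has_defect = defect.any(axis=0)
    if has_defect.any():
        last = p.n_rows - 1 - np.argmax(defect[::-1], axis=0)
        rows = np.arange(p.n_rows)[:, None]
        shadow = (rows > last[None, :]) & has_defect[None, :]

    surface_rows = np.clip(
        np.rint(surf / p.pitch_um).astype(int), 0, p.n_rows - 1
    )
    return labels, shadow, surface_rows


def rasterize_phantom(phantom: LimbusPhantom, frames=None):
    """Voxelize the phantom into ground truth and a mean-reflectivity volume.

    Returns ``(GroundTruth, reflectivity)`` where reflectivity is float32 of
    shape (n_frames, n_rows, n_cols) holding mean amplitude reflectivity
    (no speckle, no shadow attenuation).
    """
    frames = range(phantom.n_frames) if frames is None else list(frames)
    n_f = len(frames)
    labels = np.zeros((n_f, phantom.n_rows, phantom.n_cols), dtype=np.uint8)
    shadow = np.zeros_like(labels, dtype=bool)
    surface_rows = np.zeros((n_f, phantom.n_cols), dtype=int)
    for i, f in enumerate(frames):
        labels[i], shadow[i], surface_rows[i] = _rasterize_frame(phantom, f)

    lut = np.zeros(len(LABELS), dtype=np.float32)
    for name, code in LABELS.items():
        if name != "BACKGROUND":
            lut[code] = phantom.reflectivity[name]
    reflectivity = lut[labels]
    gt = GroundTruth(
        surface_rows=surface_rows,
        labels=labels,
        shadow=shadow,
        pitch_um=phantom.pitch_um,
    )
    return gt, reflectivity


def _shadow_attenuation(phantom: LimbusPhantom, gt: GroundTruth) -> np.ndarray:
    """Exponential amplitude attenuation from cumulative overlying opacity.

    Only the DEFECT is opaque; a voxel below the full defect thickness is
    attenuated by exp(-opacity * thickness) ~ 0 (a hard axial shadow)."""
    defect = gt.label_mask("DEFECT")
    path = np.cumsum(defect, axis=1) * phantom.pitch_um  # µm of defect above
    path = path - defect * phantom.pitch_um  # self-attenuation excluded
    return np.exp(-phantom.defect_opacity_per_um * path).astype(np.float32)


def render_bscan_stack(
    phantom: LimbusPhantom,
    frames=None,
    seed: int | None = 0,
    noise_sigma: float = 0.012,
):
    """Image-domain shortcut: isometric [0,1] B-scan stack straight from the
    reflectivity volume (speckle + shadow + detector noise), bypassing the
    spectral forward model.

    Returns ``(stack, GroundTruth)``; stack is float32 of shape
    (n_frames, n_rows, n_cols), ready for segmentation/visualization.
    """
    gt, refl = rasterize_phantom(phantom, frames)
    rng = np.random.default_rng(seed)
    speckle = np.abs(
        1.0 + phantom.speckle_sigma * rng.standard_normal(refl.shape)
    ).astype(np.float32)
    img = refl * speckle * _shadow_attenuation(phantom, gt)
    if noise_sigma > 0:
        img = img + noise_sigma * rng.standard_normal(img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0).astype(np.float32), gt


@dataclass
class ScattererColumn:
    """Discrete scatterers of one A-line: (optical depth µm, amplitude)."""

    depths_um: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.depths_um = np.atleast_1d(np.asarray(self.depths_um, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if self.depths_um.shape != self.amplitudes.shape:
            raise ValueError("depths and amplitudes must align")
        if self.depths_um.size and np.any(self.depths_um <= 0):
            raise ValueError("optical depths must be strictly positive")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")


def scatterer_columns(
    phantom: LimbusPhantom,
    frame: int = 0,
    seed: int | None = 0,
    amplitude_scale: float = 0.002,
) -> list[ScattererColumn]:
    """Discretize one phantom frame into per-A-line scatterer columns.

    A voxel at depth t below the frame top maps to optical path difference
    z = n * (H - t); the deepest row sits at DC, the surface at large z.
    Amplitudes carry speckle and shadow attenuation; ``amplitude_scale``
    keeps the summed fringe modulation small (near-linear detection).
    """
    gt, refl = rasterize_phantom(phantom, frames=[frame])
    rng = np.random.default_rng(seed)
    speckle = np.abs(1.0 + phantom.speckle_sigma * rng.standard_normal(refl.shape))
    amp = refl[0] * speckle[0] * _shadow_attenuation(phantom, gt)[0]
    t = (np.arange(phantom.n_rows) + 0.5) * phantom.pitch_um
    z = phantom.tissue_index * (phantom.height_um - t)
    cols = []
    for c in range(phantom.n_cols):
        keep = amp[:, c] > 1e-6
        cols.append(
            ScattererColumn(z[keep], amplitude_scale * amp[keep, c])
        )
    return cols


def synthesize_interferogram(
    columns,
    source_spectrum: np.ndarray,
    wavelength_um: np.ndarray,
    dispersion=None,
    noise_level: float = 0.0,
    seed: int | None = 0,
    frame_id: int = 0,
) -> SpectralFrame:
    """Forward model: raw spectral fringes for a set of scatterer columns.

    For scatterer j at optical depth z_j the detected spectrum is
    B(lambda)*(1 + sum_j a_j cos(2 k z_j + phi_d(k))) + eps with k = 2*pi/lambda
    and phi_d an optional dispersion phase (a DispersionModel or a callable
    of k).  ``noise_level`` is the additive Gaussian sigma relative to the
    background maximum.  Reproducible for a fixed seed.
    """
    if isinstance(columns, ScattererColumn):
        columns = [columns]
    if len(columns) == 0:
        raise ValueError("no scatterer columns given")
    lam = np.asarray(wavelength_um, dtype=float)
    bsrc = np.asarray(source_spectrum, dtype=float)
    if bsrc.shape != lam.shape:
        raise ValueError("source spectrum and wavelength grid disagree")
    if noise_level < 0:
        raise ValueError("noise level must be non-negative")
    k = 2.0 * np.pi / lam
    dk_max = float(np.abs(np.diff(k)).max())
    z_alias = np.pi / (2.0 * dk_max)
    z_all = np.concatenate([c.depths_um for c in columns if c.depths_um.size])
    if z_all.size and z_all.max() >= z_alias:
        raise ValueError(
            f"scatterer depth {z_all.max():.1f} um at or beyond the "
            f"unambiguous range {z_alias:.1f} um (local Nyquist of the "
            "wavelength sampling)"
        )
    if dispersion is None:
        phi = np.zeros_like(k)
    elif callable(dispersion):
        phi = np.asarray(dispersion(k), dtype=float)
    else:
        phi = np.asarray(dispersion.phase(k), dtype=float)

    fringes = np.empty((lam.size, len(columns)))
    for j, col in enumerate(columns):
        if col.depths_um.size:
            fringes[:, j] = (
                np.cos(2.0 * np.outer(k, col.depths_um) + phi[:, None])
                @ col.amplitudes
            )
        else:
            fringes[:, j] = 0.0
    data = bsrc[:, None] * (1.0 + fringes)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_level * bsrc.max() * rng.standard_normal(data.shape)
    return SpectralFrame(data=data, wavelength_um=lam, frame_id=frame_id)
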