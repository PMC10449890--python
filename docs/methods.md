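# Methods

This note records the models, numerical choices and limitations behind
`limbusoct`. Units are micrometres unless stated otherwise.

## Spectral forward model

The interferogram of one A-line is modeled as

    I(λ_i) = B(λ_i) · [1 + Σ_j a_j cos(2 k_i z_j + φ_d(k_i))] + ε_i

with `k = 2π/λ`, scatterer amplitudes `a_j` at optical path differences
`z_j`, a polynomial dispersion phase `φ_d(k) = c₂(k−k₀)² + c₃(k−k₀)³`, and
additive Gaussian detector noise `ε`. Detection is treated as linear (the
summed fringe modulation is kept small, `amplitude_scale = 0.002` per
voxel); autocorrelation terms between scatterers are neglected.

The source is up to three Gaussian SLDs merged by two beam combiners with
transmission:reflection ratios 0.5:0.5 and 0.7:0.3, giving component
weights t₁t₂ : r₁t₂ : r₂ = 0.35 : 0.35 : 0.30. Default SLD centers
795.4 / 852.9 / 910.4 nm with 60 nm FWHM each were solved once so the
combined spectrum has an 850.0 nm centroid and 165.2 nm FWHM, matching the
instrument class being modeled.

**Sampling window.** The camera samples 2048 pixels uniformly in
wavelength over 780–920 nm. This span was fixed by two constraints: (i)
the processed frame is 798 rows of 2 µm physical depth (1.596 mm), i.e.
2.13 mm optical at n = 1.336, which must fit inside the one-sided
uniform-k Nyquist range (here 2.62 mm); and (ii) uniform-λ sampling has a
*local* Nyquist limit π/(2·max dk) at the blue edge — 2.23 mm for this
window — which must also exceed the frame depth, or deep fringes alias
before k-linearization can help. The window truncates the 165 nm source,
so the axial resolution is ~5 µm optical (Hann-windowed) rather than the
2–3 µm a full-bandwidth spectrometer would give; no shipped check depends
on absolute resolution. `synthesize_interferogram` raises if any scatterer
is placed at or beyond the local-Nyquist depth.

**Orientation.** The sample is modeled across the zero delay on the
mirror-image side, the arrangement that puts the DC row at the bottom of
the displayed frame, the anterior surface near the top, and the deep
TM/SC/CC region nearest DC where an SD-OCT system is most sensitive. A
voxel at depth `t` below the frame top maps to `z = n·(H − t)` with `H`
the frame height; the single averaged index n = 1.336 is used both in the
forward model and in the postprocessing rescale, so the round trip is
exact by construction (no per-layer or air/tissue split — a deliberate
simplification matching the reconstruction's own assumption).

## Reconstruction chain

Stage order is fixed: subtract background → divide by normalized
background → Hann window → 2× upsample → k-linearize → dispersion correct
→ FFT → magnitude → log. Numerical choices:

- **Background floor.** The normalized background is clamped at ε = 10⁻³
  of its maximum before division, bounding band-edge amplification.
- **Upsampling.** Per column: FFT to the image domain, zero-pad to 2N with
  the Nyquist bin split symmetrically (a real input stays real), inverse
  FFT, ×2 so even output samples reproduce the input exactly for
  band-limited signals. This doubles the unambiguous depth; it cannot add
  information beyond the raw sampling.
- **k map.** The 2N interpolated samples sit at half-pixel positions of
  the camera's index→wavelength map (evaluated with a cubic spline, exact
  for grids uniform in λ or in k). The uniform-k target grid uses 2N−1
  points over the *original* k range: the trailing half-pixel sample is
  wraparound-contaminated and is dropped, and the 2N−1 midpoint grid is
  the unique choice that is both exact on an already-uniform-in-k input
  and symmetric under flipping the spectral axis. Resampling is cubic,
  real and imaginary parts independently; extrapolation raises.
- **Dispersion correction** multiplies by `exp(−i φ(k))` and requires a
  complex spectrum (a real input signals a stage-order bug). Correcting
  the real fringe's conjugate term doubles its phase error, but that term
  lands in the discarded half of the transform.
- **Dispersion estimation** minimizes the Shannon entropy of the
  reconstructed A-line intensity over (c₂, c₃) with Nelder–Mead from
  (0,0), coefficients scaled so a unit step changes the band-edge phase by
  ~1 rad, and a 10⁻⁹·|c₃| tie-break toward the smaller cubic term. The
  entropy is evaluated on a 4× zero-padded transform: without padding the
  minimum is displaced by up to ~10% in c₃ because the continuous PSF peak
  drifts between DFT bins (scalloping); with padding the minimum sits at
  the injected coefficients to <0.1% at every mirror depth tested.
- **Log display** is 20·log₁₀(|·| + δ) with δ = 10⁻¹² of the frame
  maximum; absolute display scaling is arbitrary and every quantitative
  check works on linear magnitudes or on positions.

Postprocessing divides the axial pitch by n = 1.336, resamples bilinearly
to 2 µm isometric pixels, keeps the 798 rows adjacent to DC (the block
containing the surface and all tissue; the upsampling extension above it
is empty), applies a 3×3 median filter with reflective boundaries (no
dark-edge artifacts feeding the gradient cost), and rescales to [0,1]
(constant images map to zero with a warning).

## Segmentation

Cost image: `1 − normalized positive vertical gradient`, so dark-above /
bright-below transitions are cheap. The boundary is the exact minimum-cost
connected path (dynamic programming; vertical step ≤ 2 rows per column —
the surface slope at 2 µm pitch is gentle), ties broken toward the
shallower row since the anterior surface is the first interface. Frame 0
is seeded by ≥2 manual points spanning ≥50% of the width, interpolated
monotone-cubically, refined by one banded pass, then fitted with a
degree-9 polynomial over the column index. Each fitted boundary defines a
±20 µm band for the next frame (frames are 10 µm apart). The band is an
offset band around the previous boundary — equivalent to searching a flat
band in the flattened frame. If the raw path presses against the band edge
on >25% of columns a divergence warning is issued; an empty or
unconnectable band raises with the frame index.

## Rendering and projections

Depth encoding: H = (2/3)·min(d/Dmax, 1), S = 1, V = image intensity,
converted by the standard hexcone HSV→RGB; above-surface pixels are
exactly black. Dmax defaults to the full below-surface depth of the frame.
Flattening shifts each column by the rounded boundary row; vacated rows
are zero-filled and exact zeros are treated as missing when taking slab
minima, so fill can never masquerade as a dark lumen (a slab that is
entirely fill projects to 0). Axis projections implement max, min, mean,
median, sum and population-convention std. Panoramas concatenate
equal-height circumferential frames, cropping a stated overlap.

## The phantom

The synthetic scene is the package's study condition: 798 × 500 px frames
(2 µm isometric), 250 frames at 10 µm spacing by default (tests and the
acceptance script render 16 frames — accuracy is per-frame, so the
scale-down changes runtime, not difficulty). Geometry, all in physical µm:
a curved, tilted anterior surface (base 150, sag 120, tilt 40, 30 drift
across the stack); sclera below it (amplitude reflectivity 0.55); an AC
wedge (0.03) with iris (0.40) on the cornea side; a TM wedge from 650 µm
below the surface thickening 40→120 µm toward the sclera (0.35); the SC
lumen as a 130 × 28 µm half-axis ellipse centered 606 µm below the surface
(0.06), wobbling ±25 µm along the stack — placed so the standard en-face
slab (rows 286–320 below the flattened surface) brackets the canal; two
collector-channel tubes (~30 µm calibre, 0.10) above the canal plus a
branch in the middle frames; and an opaque surface defect (0.85, opacity
0.5 µm⁻¹) that casts a hard axial shadow. The invariant SC < TM < sclera
reflectivity is enforced. Speckle is multiplicative amplitude jitter
|1 + 0.35·N(0,1)| per voxel plus additive Gaussian detector noise
(σ = 0.012 in the image shortcut) — the simplest model that produces
OCT-like texture for segmentation testing.

What the phantom does *not* emulate: correlated (fully developed) speckle
statistics, confocal/sensitivity roll-off, refraction at the surface,
polarization, motion. Passing tests therefore demonstrate the correctness
of the algorithms under realistic geometry and noise ordering, not
clinical performance on real tissue.

Two rendering routes: the spectral route (scatterer columns → fringes →
full reconstruction) exercises the physics end to end; the image-domain
shortcut rasterizes reflectivity straight into [0,1] isometric B-scans and
is used wherever only the segmentation/visualization stages are under
test. The en-face SC detector used in checks thresholds the minimum
projection at the lumen's mean reflectivity (0.06), a scene parameter.

## Scan geometry

The crossline waveform alternates a radial and a circumferential sweep
joined by bowtie hypotenuses; the circumferential drive is exactly zero
during radial sweeps and vice versa. Sweeps get one sample per 2 µm of
travel at the 20 kHz A-line rate; transitions get 10% of a sweep's samples
(the split is a free choice — no timing breakdown is published) and are
labeled non-imaging. Volume plans place frames at 0, 10, …, 2490 µm over a
2.5 mm translation; angular coverage of a chord d on a ring of diameter D
is θ = 2·atan(d/D) (3.5 mm on the 11.8 mm mean spur-to-spur canal ring →
33°).

## Determinism and I/O

All randomness flows from one integer seed through
`numpy.random.default_rng`; reruns of the pipeline with the same config
and seed are byte-identical (the TIFF writer embeds no timestamps).
Volumes travel as multi-page TIFF with JSON sidecars (pitches,
quantization range, seed, provenance); float stacks are stored as uint16
with the affine range recorded, which costs <1 LSB of round-trip error.

## Known limitations

- Dispersion is modeled and estimated as quadratic + cubic only; higher
  orders would bias the entropy search.
- The segmentation tracks a single (anterior) boundary; posterior surfaces
  and SC walls are out of scope.
- The 140 nm spectrometer window sacrifices axial resolution relative to
  the full 165 nm source bandwidth (see Sampling window above).
- Circumferential frames in the pipeline's panorama are y–z slices of the
  radial stack rather than independently scanned lines; the bowtie
  waveform generator produces the trajectory but no separate image
  formation model for it.
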