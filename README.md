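# limbusoct

Spectral-domain OCT simulation, reconstruction and visualization for
iridocorneal-angle (limbus) imaging.

The iridocorneal angle — where the iris meets the cornea — contains the
drainage machinery of the eye: the trabecular meshwork (TM), the ring-shaped
Schlemm's canal (SC) outside it, and the thin collector channels (CCs) that
carry aqueous humor to the episcleral veins. Increased outflow resistance in
this region drives glaucoma, so visualizing TM/SC/CC in 3D at micron scale
matters both for diagnosis and for targeting trabecular surgery. This
package implements the full computational chain of a high-resolution
spectral-domain OCT (SD-OCT) limbus-imaging system, for people developing
or validating such pipelines: a parametric limbus phantom with a spectral
forward model (so every stage is testable without tissue), the B-scan
reconstruction chain, semi-automatic anterior-surface segmentation,
depth-encoded color rendering, flattening/en-face/axis projections, and
crossline scan-geometry utilities.

## The processing chain

A raw frame is a matrix of spectral interferograms `I(λ_i, x)` (2048
spectral pixels × 500 lateral positions by default). For a scatterer at
optical path difference `z` the detected spectrum is

    I(λ) = B(λ) · [1 + Σ_j a_j cos(2 k z_j + φ_d(k))],   k = 2π/λ,

with `B` the source envelope and `φ_d(k) = c₂(k−k₀)² + c₃(k−k₀)³` the
residual system dispersion. Reconstruction runs, per A-line:

1. subtract the background spectrum (sample arm blocked),
2. divide by the normalized ([0,1]) background to flatten the envelope,
3. Hann window,
4. 2× spectral upsampling by zero-padding in the image domain (doubles the
   unambiguous depth so detail near the Nyquist limit is preserved),
5. k-linearization: cubic resampling from the uniform-wavelength camera
   grid onto a uniform wavenumber grid,
6. dispersion compensation: multiply by `exp(−i φ(k))`, with `(c₂, c₃)`
   estimated from mirror acquisitions by minimizing the entropy of the
   reconstructed A-line intensity,
7. FFT, magnitude, log — with the DC (zero-delay) row placed at the
   *bottom* of the frame, the anterior surface near the top, and the deep
   TM/SC/CC structures in the sensitive region near DC.

Frames are then scaled by the averaged tissue index (n = 1.336), resampled
to isometric 2 µm pixels (798 × 500 px per frame), median-filtered (3×3)
and rescaled to [0,1]. The anterior surface is segmented semi-automatically:
manual seeds on the first frame, then for each subsequent frame an exact
dynamic-programming shortest path on a gradient cost image inside a ±20 µm
band around the previous frame's boundary, smoothed by a degree-9
polynomial. Depth below the boundary is painted into HSV hue on [0, 2/3]
(red → blue), the volume is flattened along the boundary, and en-face
images are minimum projections over a slab of constant depth below the
surface, where the low-backscatter SC lumen appears as a dark trough.

## Worked example

`examples/` holds one short script per capability. For instance:

```sh
$ python examples/02_dispersion_calibration.py
injected  (c2, c3) = (30.000, 10.000)
recovered (c2, c3) = (29.999, 9.998)
PSF FWHM: transform-limited 2.08 rows, uncompensated 6.69, compensated 2.08
```

Dispersion injected into simulated mirror fringes is recovered to a
fraction of a percent, and the compensated axial point spread function
returns to the transform-limited width (2.08 rows ≈ 5.3 µm optical here;
uncompensated it was 3× wider).

```sh
$ python examples/04_depth_encoding_enface.py
depth-encoded frame: RGB (798, 500, 3), hue ceiling at 1463 um below the surface
en-face slab rows 286-320: SC trough mean 0.017 vs elsewhere 0.071
SC footprint overlap with truth: 99.7%
```

On the synthetic limbus stack the segmented-and-flattened en-face minimum
projection shows the canal lumen about 4× darker than the surrounding
sclera, and the detected dark footprint covers 99.7% of the true canal.

A thin CLI mirrors the stages (`limbusoct simulate|reconstruct|segment|
render|project|scanplan|run`); `limbusoct run --seed 1 --out artifacts/`
produces the full deterministic artifact tree (B-scans, boundary CSV,
depth-encoded RGB stack, en-face, six axis projections, panorama).

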