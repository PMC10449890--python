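"""Synthesize a mirror interferogram and reconstruct its A-line.

Builds the three-SLD source (50:50 and 70:30 beam combiners), places a
mirror at a known optical depth, runs the full reconstruction chain
(background removal, Hann window, 2x upsampling, k-linearization, FFT) and
reports where the peak landed.
"""

import numpy as np

from limbusoct.phantom import (
    ScattererColumn,
    SourceSpectrumModel,
    build_source_spectrum,
    synthesize_interferogram,
)
from limbusoct.recon import BackgroundSpectrum, KMap, reconstruct_bscan

model = SourceSpectrumModel()
lam = np.linspace(0.780, 0.920, 2048)  # spectrometer window, um
source = build_source_spectrum(model, lam)
background = BackgroundSpectrum(source)
kmap = KMap(lam)

wide = np.linspace(0.70, 1.00, 8192)
s = build_source_spectrum(model, wide)
centroid = np.trapezoid(s * wide, wide) / np.trapezoid(s, wide)
above = wide[s >= s.max() / 2]
print(f"combined source: centroid {1000 * centroid:.1f} nm, "
      f"FWHM {1000 * (above.max() - above.min()):.1f} nm "
      f"(component weights {model.component_weights()})")

z_true = 800.0  # optical path difference of the mirror, um
frame = synthesize_interferogram(ScattererColumn([z_true], [0.05]), source, lam)
image = reconstruct_bscan(frame, background, kmap)

row = int(np.argmax(image.data[:, 0]))
z_found = image.depth_of_row(row)
print(f"mirror placed at {z_true:.1f} um -> peak at row {row} "
      f"= {z_found:.1f} um ({image.axial_pitch_um:.2f} um/row)")
print("peak localization error:",
      f"{abs(z_found - z_true) / image.axial_pitch_um:.2f} rows")
# The error stays below one row for any depth inside the unambiguous range;
# the DC (zero-delay) row sits at the bottom of the frame.
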