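"""Crossline (bowtie) scan trajectory and volume coverage arithmetic.

Generates one period of the alternating radial/circumferential waveform,
plans the 250-frame translated volume, and expresses the circumferential
coverage as an angle on the ring-shaped Schlemm's canal.
"""

from limbusoct.scangeom import (
    VolumeScanPlan,
    angular_coverage,
    make_bowtie_waveform,
    plan_volume,
)

wf = make_bowtie_waveform(radial_length_mm=1.0, circ_length_mm=1.0,
                          aline_rate_hz=20_000.0, lateral_pitch_um=2.0)
counts = {lbl: int((wf.label == lbl).sum()) for lbl in
          ("radial", "circumferential", "transition")}
print(f"one bowtie period: {len(wf)} samples at 20 kHz "
      f"({counts['radial']} radial, {counts['circumferential']} circumferential, "
      f"{counts['transition']} transition)")
print(f"largest per-sample beam step: {1000 * wf.max_step():.1f} um")

plan = VolumeScanPlan()  # 10 um spacing over 2.5 mm, 1.0 mm frames
table = plan_volume(plan)
print(f"volume plan: {plan.n_frames} frames x {plan.alines_per_frame} A-lines, "
      f"offsets {table.y_offset_um.iloc[0]:.0f}..{table.y_offset_um.iloc[-1]:.0f} um")

coverage_mm = plan.translation_mm + plan.frame_width_mm
theta = angular_coverage(coverage_mm, 11.8)
print(f"circumferential coverage: {coverage_mm:.1f} mm = {theta:.1f} deg of an "
      f"11.8 mm spur-to-spur ring")
# 2.5 mm of stage travel plus the 1.0 mm line itself sweeps about a third
# of a quadrant of the canal's circumference.
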