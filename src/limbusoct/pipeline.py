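"""End-to-end orchestration: phantom -> B-scans -> segmentation -> rendering.

``run_pipeline`` produces a deterministic artifact tree from one config and
one seed: the simulated B-scan stack, the propagated surface boundaries,
depth-encoded RGB frames, the flattened-volume en-face projection, the six
axis intensity projections, and a circumferential panorama.  Re-running
with the same config and seed reproduces the outputs byte for byte.

The manual-seeding step of the segmentation is stood in for by sampling
the phantom's ground-truth surface at five columns — the synthetic
equivalent of the operator's clicks on the first frame.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as lio
from .config import PipelineConfig
from .phantom import LimbusPhantom, render_bscan_stack
from .render import (
    PROJECTION_KINDS,
    concat_panorama,
    depth_encode,
    enface_min_projection,
    flatten_volume,
    mask_above_surface,
)
from .segment import boundaries_to_frame, propagate_stack, segment_first_frame

__all__ = ["run_pipeline"]


def _seed_points(surface_rows: np.ndarray, n_seeds: int = 5) -> np.ndarray:
    cols = np.linspace(0, surface_rows.size - 1, n_seeds).round().astype(int)
    return np.column_stack([cols, surface_rows[cols]]).astype(float)


def run_pipeline(config: PipelineConfig, out_dir=None) -> Path:
    """Run the full synthetic pipeline; returns the artifact directory."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    phantom = LimbusPhantom(
        n_rows=config.n_rows, n_cols=config.n_cols, n_frames=config.n_frames
    )
    try:
        stack, gt = render_bscan_stack(
            phantom, seed=config.seed, noise_sigma=config.noise_sigma
        )
    except Exception as exc:
        raise RuntimeError(f"stage simulate: {exc}") from exc

    u16, lo, hi = lio.quantize16(stack)
    lio.write_stack(
        u16,
        out / "bscans.tiff",
        {"pitch_um": config.pitch_um, "quant_lo": lo, "quant_hi": hi,
         "seed": config.seed},
    )

    try:
        seeds = _seed_points(gt.surface_rows[0])
        first = segment_first_frame(
            stack[0], seeds, band_um=config.band_um, degree=config.poly_degree,
            step=config.path_step, pitch_um=config.pitch_um,
        )
        boundaries = propagate_stack(
            stack, first, band_um=config.band_um, degree=config.poly_degree,
            step=config.path_step,
        )
    except Exception as exc:
        raise RuntimeError(f"stage segment: {exc}") from exc

    boundaries_to_frame(boundaries).to_csv(out / "boundaries.csv", index=False)

    try:
        rgb = np.stack(
            [
                depth_encode(
                    mask_above_surface(stack[f], boundaries[f]),
                    boundaries[f],
                    depth_scale_um=config.depth_scale_um,
                    pitch_um=config.pitch_um,
                ).to_uint8()
                for f in range(len(boundaries))
            ]
        )
    except Exception as exc:
        raise RuntimeError(f"stage depth_encode: {exc}") from exc
    lio.write_stack(rgb, out / "depth_rgb.tiff", {"hue_ceiling": config.hue_ceiling})

    try:
        flat = flatten_volume(stack, boundaries)
        r1, r2 = config.slab_rows
        r2 = min(r2, flat.data.shape[1] - 1)
        enface = enface_min_projection(flat, (min(r1, r2), r2))
    except Exception as exc:
        raise RuntimeError(f"stage enface: {exc}") from exc
    u16, lo, hi = lio.quantize16(enface)
    lio.write_stack(
        u16[None], out / "enface.tiff",
        {"slab_rows": [int(min(r1, r2)), int(r2)], "quant_lo": lo, "quant_hi": hi},
    )

    proj_dir = out / "projections"
    try:
        from .render import intensity_projection

        for kind in PROJECTION_KINDS:
            p = intensity_projection(stack, axis=config.projection_axis, kind=kind)
            u16, lo, hi = lio.quantize16(p)
            lio.write_stack(
                u16[None], proj_dir / f"{kind}.tiff",
                {"kind": kind, "axis": config.projection_axis,
                 "quant_lo": lo, "quant_hi": hi},
            )
    except Exception as exc:
        raise RuntimeError(f"stage projections: {exc}") from exc

    try:
        # circumferential (y-z) views at three lateral positions across the
        # Schlemm's-canal region, concatenated side by side
        xs = [int(phantom.sc_center_x_um / config.pitch_um) + off for off in (-40, 0, 40)]
        xs = [min(max(x, 0), stack.shape[2] - 1) for x in xs]
        panorama = concat_panorama([stack[:, :, x].T for x in xs])
    except Exception as exc:
        raise RuntimeError(f"stage panorama: {exc}") from exc
    u16, lo, hi = lio.quantize16(panorama)
    lio.write_stack(u16[None], out / "panorama.tiff",
                    {"quant_lo": lo, "quant_hi": hi})

    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True)
    )
    (out / "log.txt").write_text(
        f"config_hash={config.hash()}\nseed={config.seed}\n"
        f"frames={config.n_frames} rows={config.n_rows} cols={config.n_cols}\n"
    )
    return out
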