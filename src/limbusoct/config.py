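"""Pipeline configuration: every stage parameter in one serializable tree.

Defaults reproduce the standard acquisition/processing settings: 2048
spectral pixels, Hann window, 2x spectral upsampling, tissue index 1.336,
2 µm isometric pixels, 3x3 median filter, +/-20 µm segmentation band,
degree-9 boundary polynomial, hue ceiling 2/3, en-face slab rows 286-320.
Unknown keys are rejected on load so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # simulation
    seed: int = 0
    n_frames: int = 16
    n_rows: int = 798
    n_cols: int = 500
    noise_sigma: float = 0.012

    # reconstruction
    n_spectral_pixels: int = 2048
    wavelength_range_um: tuple = (0.780, 0.920)
    upsample: bool = True

    # postprocessing
    tissue_index: float = 1.336
    pitch_um: float = 2.0
    crop_rows: int = 798
    median_filter: bool = True

    # segmentation
    band_um: float = 20.0
    poly_degree: int = 9
    path_step: int = 2

    # rendering / projections
    hue_ceiling: float = 2.0 / 3.0
    depth_scale_um: float | None = None
    slab_rows: tuple = (286, 320)
    projection_kind: str = "min"
    projection_axis: int = 0

    # paths
    out_dir: str = "limbusoct_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wavelength_range_um"] = list(self.wavelength_range_um)
        d["slab_rows"] = list(self.slab_rows)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("wavelength_range_um", "slab_rows"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return PipelineConfig.from_dict(data or {})


def save_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    else:
        path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    return path
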