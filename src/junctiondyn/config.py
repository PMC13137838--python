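"""Pipeline configuration: a YAML-serialisable bundle of the calibration
and per-stage parameters shared by the command-line entry points."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.53
    frame_interval: float = 1.0
    frame_interval_unit: str = "min"
    segmentation: dict = field(
        default_factory=lambda: {
            "ridge_sigma_px": 2.0,
            "h_minima": 0.20,
            "min_cell_area_px": 400,
            "ridge_weight": 0.3,
            "boundary_merge_frac": 0.5,
        }
    )
    band_halfwidth_px: int = 5
    dmean_aggregation: str = "sum"  # sum | mean
    border_distance_metric: str = "nn_mean"  # nn_mean | hausdorff
    gradient_sigma_px: float = 1.0
    window_sigma_px: float = 4.0
    recoil_line: dict = field(
        default_factory=lambda: {
            "x0": 0.0, "y0": 0.0, "x1": 0.0, "y1": 0.0,
            "width_px": 1, "cut_frame": 1,
        }
    )
    seed: int = 0
    output_dir: str = "."

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval / 60.0 if self.frame_interval_unit == "s" else self.frame_interval

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
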