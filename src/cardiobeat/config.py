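"""Run configuration: every tunable of the pipeline with its default.

The defaults are the package's calibrated study conditions; a YAML file can
override any subset.  A short hash of the resolved configuration is stamped
into every output artifact for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # reference-point grid
    grid_spacing: float = 20.0
    grid_margin: float | None = None  # None -> spacing / 2

    # Lucas-Kanade tracking
    lk_window: int = 21
    pyramid_levels: int = 3
    alpha: float = 0.05  # px/frame-step noise threshold on distance steps

    # peak analysis
    prominence_frac: float = 0.2
    min_prominence_px: float = 0.9  # median peak-prominence gate, px
    f_max: float = 5.0  # beats/s physiological ceiling

    # well segmentation
    roi_padding: float = 10.0
    lightness_lut: list = field(
        default_factory=lambda: [[0.25, 0.95], [0.5, 0.90], [0.75, 0.85], [1.01, 0.80]]
    )
    min_component_area: float | None = None  # None -> 0.05% of ROI area

    # dose-response
    bootstrap_reps: int = 1000
    ci_level: float = 0.90
    bmr_grid: list = field(default_factory=lambda: [20, 30, 50])

    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return Path(path)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def lut_tuple(self) -> tuple:
        return tuple((float(a), float(b)) for a, b in self.lightness_lut)
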