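"""Run configuration: one YAML-serializable record shared by all commands."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline parameters with their documented ranges and defaults.

    The numeric defaults are the pipeline's operating point: 0.25 µm/px
    scan resolution, 7 µm² noise floor, karyomegaly thresholds 42.3 and
    50.5 µm², IoU ≥ 0.5 object matching, 70 % target sensitivity and a
    250-day follow-up horizon.
    """

    images_dir: str = "images"
    masks_dir: str = "masks"
    annotations_dir: str = "annotations"
    outcomes_csv: str = "outcomes.csv"
    output_dir: str = "out"
    resolution_um_per_px: float = 0.25
    min_area_um2: float = 7.0
    karyomegaly_p90_um2: float = 42.3
    karyomegaly_twice_median_um2: float = 50.5
    match_criterion: str = "iou"
    iou_threshold: float = 0.5
    target_sensitivity: float = 0.70
    horizon_days: float = 250.0
    grid_min_n: int = 100
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be non-negative")
        if not 0.0 < self.target_sensitivity <= 1.0:
            raise ValueError("target_sensitivity must be in (0, 1]")
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must be in (0, 1]")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be positive")
        if self.match_criterion not in ("iou", "centroid"):
            raise ValueError("match_criterion must be 'iou' or 'centroid'")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
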