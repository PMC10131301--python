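"""Run configuration: every stage parameter with its field default, loadable
from YAML/JSON and round-trippable.

Defaults mirror the field protocol: 300 kHz sampling, 2 m near-array
exclusion, 0.5 m localisation-error cap, pulse-deviation cutoff 15, 20 cm
voxels, 10-point vegetation-voxel threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # acoustics
    sample_rate: float = 300_000.0
    band_low_hz: float = 15_000.0
    band_high_hz: float = 120_000.0
    detect_threshold: float = 8.0
    holdoff_s: float = 0.020
    speed_of_sound: float = 343.0
    min_correlation: float = 0.35
    # localisation filters
    min_range_m: float = 2.0
    max_error_m: float = 0.5
    # lidar
    max_deviation: float = 15.0
    voxel_edge_m: float = 0.20
    min_veg_count: int = 10
    # tracks
    track_max_gap_s: float = 1.0
    track_max_speed_ms: float = 20.0
    track_min_positions: int = 3
    # analysis
    lamppost_mode: str = "horizontal"
    lamp_height_m: float = 4.0
    # scenario
    scenario: str = "corridor"
    duration_s: float = 16.0
    call_rate_hz: float = 8.0
    snr_db: float = 30.0
    point_density: float = 800.0
    seed: int = 0
    # paths
    output_dir: str = "batrack_out"

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_low_hz, self.band_high_hz)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config with precedence: explicit overrides > file > defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        ) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
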