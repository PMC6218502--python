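"""Pipeline configuration: every tunable with documented defaults, YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features.extract import ExtractionConfig
from .features.events import GaitEventParams
from .preprocess import FilterSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # paths
    input_dir: str = ""
    output_dir: str = "fallkit_out"
    simulate: bool = True

    # simulated cohort shape (signal-level batteries)
    n_nonfaller: int = 10
    n_faller: int = 10

    # filtering
    filter_order: int = 4
    filter_cutoff_hz: float = 20.0
    tilt_gravity_cutoff_hz: float = 0.5
    theta_limit_deg: float = 12.5

    # gait event detection
    gait_smooth_cutoff_hz: float = 10.0
    gait_min_peak_amp: float = 50.0
    gait_rel_peak_frac: float = 0.4
    gait_turn_gap_factor: float = 1.75
    walkway_distance_m: float = 3.0
    sts5_onset_frac: float = 0.1

    # screening
    alpha: float = 0.05
    marginal_alpha: float = 0.10

    # cross-validation
    cv_folds: int = 10
    cv_repeats: int = 10

    seed: int = 0

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            filter_spec=FilterSpec(self.filter_order, self.filter_cutoff_hz),
            gravity_cutoff_hz=self.tilt_gravity_cutoff_hz,
            theta_limit_deg=self.theta_limit_deg,
            gait_params=GaitEventParams(
                smooth_cutoff_hz=self.gait_smooth_cutoff_hz,
                min_peak_amp=self.gait_min_peak_amp,
                rel_peak_frac=self.gait_rel_peak_frac,
                turn_gap_factor=self.gait_turn_gap_factor,
            ),
            walkway_distance_m=self.walkway_distance_m,
            sts5_onset_frac=self.sts5_onset_frac,
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
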