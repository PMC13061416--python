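"""Run configuration: the defaults that define the assay.

The defaults encode the assay constants: 0.87 fps larval video, sleep =
>= 12 consecutive inactive frames, adult sleep = >= 5 min without beam
crossing, and the 90 s ON / 30 s OFF deprivation cycle after a 1-h
baseline. Every pipeline run serializes its effective configuration next to
its outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ConfigError


@dataclass
class RunConfig:
    fps: float = 0.87
    min_sleep_frames: int = 12
    adult_min_gap_min: int = 5
    deprivation_baseline_s: float = 3600.0
    deprivation_on_s: float = 90.0
    deprivation_off_s: float = 30.0
    deprivation_session_s: float = 3600.0
    pixel_size_mm: float = 0.1
    noise_floor: float = 10.0
    seed: int = 0
    lights_on: str = "09:00"
    lights_off: str = "21:00"
    # Bonferroni family per comparison set, declared explicitly:
    # {"family_name": ["group_a|group_b", ...]}
    comparison_families: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.min_sleep_frames < 1:
            raise ConfigError("min_sleep_frames must be >= 1")
        if self.adult_min_gap_min < 1:
            raise ConfigError("adult_min_gap_min must be >= 1")
        if self.pixel_size_mm is not None and self.pixel_size_mm <= 0:
            raise ConfigError("pixel_size_mm must be positive")
        return self

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
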