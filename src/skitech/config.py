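"""Pipeline configuration with YAML round-trip.

Defaults reproduce the pipeline constants: 0.25 s detection filter,
0.0875 s feature filter, 30 resampled points per axis, hidden layers
50/10/20 and 20 training restarts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import HIDDEN_LAYERS, TrainConfig
from .cycles import MIN_PEAK_SEPARATION_S, PROMINENCE_FRACTION
from .features import N_RESAMPLED

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    detect_sigma_s: float = 0.25
    feature_sigma_s: float = 0.0875
    resample_points: int = N_RESAMPLED
    min_cycle_separation_s: float = MIN_PEAK_SEPARATION_S
    prominence_fraction: float = PROMINENCE_FRACTION
    hidden_layers: tuple[int, ...] = HIDDEN_LAYERS
    restarts: int = 20
    alpha_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    max_iter: int = 200
    seed: int = 0
    gnss_offset_s: float = 0.0
    # benchmark sizes used by the `run` subcommand
    train_cycles_per_class: int = 200
    val_cycles_per_class: int = 50
    test_cycles_per_class: int = 50
    noise: float = 0.1

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(self.hidden_layers)
        self.alpha_grid = tuple(self.alpha_grid)
        if self.detect_sigma_s <= 0 or self.feature_sigma_s <= 0:
            raise ValueError("filter sigmas must be positive")
        if self.resample_points < 2:
            raise ValueError("resample_points must be >= 2")

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            restarts=self.restarts,
            alpha_grid=self.alpha_grid,
            max_iter=self.max_iter,
            seed=self.seed,
            hidden_layers=self.hidden_layers,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["hidden_layers"] = list(self.hidden_layers)
        data["alpha_grid"] = [float(a) for a in self.alpha_grid]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
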