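"""Pipeline configuration: defaults, YAML round-trip, and overrides.

The defaults reproduce the analysis constants exactly: PPG analyzed at
64 Hz and EDA at 4 Hz, inter-beat intervals valid in 40-180 bpm, at
least 40 valid intervals per minute block, a 75:25 stratified split and
5-fold cross-validation, and an SGD linear model with hinge loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .simulate import ReactivityConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]

CONFIG_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    version: int = CONFIG_VERSION
    ppg_hz: float = 64.0
    eda_hz: float = 4.0
    min_bpm: float = 40.0
    max_bpm: float = 180.0
    min_valid_ibi: int = 40
    train_fraction: float = 0.75
    n_folds: int = 5
    epochs: int = 1000
    l2: float = 1e-4
    loss: str = "hinge"
    seed: int = 0
    cohort_size: int = 20
    reactivity: ReactivityConfig = field(default_factory=ReactivityConfig)

    def __post_init__(self) -> None:
        if self.version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {self.version}")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")

    def with_overrides(self, **overrides: Any) -> "PipelineConfig":
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    data = dict(data)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "reactivity" in data and isinstance(data["reactivity"], Mapping):
        rknown = {f.name for f in fields(ReactivityConfig)}
        runknown = set(data["reactivity"]) - rknown
        if runknown:
            raise ValueError(f"unknown reactivity keys: {sorted(runknown)}")
        data["reactivity"] = ReactivityConfig(**data["reactivity"])
    return PipelineConfig(**data)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Config from a YAML file, or the defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return _from_dict(raw)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize the effective configuration next to output artifacts."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )
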