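"""Run configuration: structured YAML with strict key validation."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .axial import HarmonyConfig, MiConfig
from .longitudinal import DtwConfig
from .preprocessing import PreprocessConfig
from .synthetic import DistortionSpec

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {
    "preprocess": PreprocessConfig,
    "dtw": DtwConfig,
    "mi": MiConfig,
    "harmony": HarmonyConfig,
    "simulate": DistortionSpec,
}


def _build(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        coerced[key] = value
    return cls(**coerced)


@dataclasses.dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    dtw: DtwConfig = dataclasses.field(default_factory=DtwConfig)
    mi: MiConfig = dataclasses.field(default_factory=MiConfig)
    harmony: HarmonyConfig = dataclasses.field(default_factory=HarmonyConfig)
    simulate: DistortionSpec = dataclasses.field(default_factory=DistortionSpec)
    global_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "global_seed": self.global_seed,
            **{name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS},
        }

    def dump(self, path: str | Path) -> None:
        """Write the fully resolved configuration (defaults included)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; unknown sections or keys raise."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(_SECTIONS) - {"global_seed"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {
        name: _build(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(global_seed=int(data.get("global_seed", 0)), **kwargs)
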