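"""Layered run configuration: defaults -> YAML file -> CLI overrides.

A :class:`RunConfig` nests the simulation, model and training sections; every
default is the published value where one exists.  Unknown keys are rejected
so that typos fail loudly, and the fully resolved config is serialized into
every output directory for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossWeights
from .network import ModelConfig
from .simulate import SimulationConfig
from .training import TrainConfig


def _build(cls, raw: dict, nested: dict | None = None):
    nested = nested or {}
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(raw)
    for key, sub_cls in nested.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = _build(sub_cls, kwargs[key])
    for key in ("trial_span", "split_ratio"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - {"simulation", "model", "training"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            simulation=_build(SimulationConfig, raw.get("simulation", {})),
            model=_build(ModelConfig, raw.get("model", {})),
            training=_build(TrainConfig, raw.get("training", {}),
                            nested={"loss_weights": LossWeights}),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"]["trial_span"] = list(out["simulation"]["trial_span"])
        out["training"]["split_ratio"] = list(out["training"]["split_ratio"])
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def write(self, directory: str | Path) -> Path:
        path = Path(directory) / "run_config.json"
        payload = self.to_dict()
        payload["config_hash"] = self.digest()
        path.write_text(json.dumps(payload, indent=2))
        return path
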