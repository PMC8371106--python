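"""Run configuration: one YAML file with per-stage sections.

The global ``seed`` is propagated into every stochastic sub-config that was
not given an explicit seed of its own, so a single integer reproduces an
entire run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml

from .augment import AugmentationConfig, SplitSpec
from .classical import ClassicalConfig
from .cnn import TrainConfig
from .synthgen import SynthConfig


def _build(cls, data: Optional[dict]):
    data = dict(data or {})
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    # YAML gives lists where dataclasses expect tuples
    for f in fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


@dataclass
class RunConfig:
    seed: int = 0
    out_root: str = "run"
    n_per_class: int = 30
    log_level: str = "INFO"
    synth: SynthConfig = field(default_factory=SynthConfig)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    classical: ClassicalConfig = field(default_factory=ClassicalConfig)

    def __post_init__(self) -> None:
        # one global seed drives every stage unless a stage overrides it
        for sub in (self.synth, self.augment, self.split, self.train):
            if sub.seed == 0:
                sub.seed = self.seed
        self.validate()

    def validate(self) -> None:
        self.synth.validate()
        self.augment.validate()
        self.split.validate()
        self.train.validate()
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for name, sub_cls in [("synth", SynthConfig),
                              ("augment", AugmentationConfig),
                              ("split", SplitSpec), ("train", TrainConfig),
                              ("classical", ClassicalConfig)]:
            if name in data:
                kwargs[name] = _build(sub_cls, data.pop(name))
        for key in ("seed", "out_root", "n_per_class", "log_level"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown config fields: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
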