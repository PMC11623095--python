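"""Run configuration: one flat, fully serialized record of a training or
evaluation run (model + optimizer + data settings), loadable from YAML with
CLI overrides.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

from .model import StagePlan
from .train import TrainConfig

__all__ = ["RunConfig", "SIZE_PRESETS"]

SIZE_PRESETS = ("smoke",)


@dataclass(frozen=True)
class RunConfig:
    input_side: int = 224
    num_classes: int = 9
    widths: tuple = (64, 128, 320, 512)
    depths: tuple = (2, 2, 2, 2)
    groups: tuple = (1, 2, 5, 8)
    bridge_depth: int = 4
    fusion: str = "max"
    preset: str = "default"  # dilation schedule: default | low | high
    loss: str = "hybrid"
    lam: float = 0.6
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    poly_power: float = 0.9
    epochs: int = 400
    iters: int | None = None
    batch_size: int = 24
    val_interval: int = 100
    augment: bool = True
    seed: int = 0

    def stage_plan(self) -> StagePlan:
        return StagePlan(
            widths=tuple(self.widths),
            depths=tuple(self.depths),
            groups=tuple(self.groups),
            bridge_depth=self.bridge_depth,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            input_side=self.input_side,
            base_lr=self.lr,
            poly_power=self.poly_power,
            max_epochs=self.epochs,
            max_iters=self.iters,
            batch_size=self.batch_size,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            lam=self.lam,
            loss_mode=self.loss,
            seed=self.seed,
            augment=self.augment,
            val_interval=self.val_interval,
        )

    def with_overrides(self, **kwargs) -> "RunConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **clean)

    def apply_size_preset(self, name: str) -> "RunConfig":
        """'smoke' shrinks the plan to a CPU-scale model on 64×64 inputs."""
        if name != "smoke":
            raise ValueError(f"unknown size preset {name!r}; valid: {SIZE_PRESETS}")
        return replace(
            self,
            input_side=64,
            widths=(16, 32, 64, 128),
            depths=(1, 1, 1, 1),
            groups=(2, 2, 4, 8),
            bridge_depth=2,
            batch_size=8,
            iters=300 if self.iters is None else self.iters,
            val_interval=50,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("widths", "depths", "groups"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("widths", "depths", "groups"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
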