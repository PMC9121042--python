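"""Run configuration: one YAML document tying all stages together."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import VSTConfig
from .saliency import SaliencyConfig
from .training import TrainConfig


@dataclass
class RunConfig:
    data_dir: str = "data"
    output_dir: str = "runs"
    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)
    model: VSTConfig = field(default_factory=VSTConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval_spacing_mm: tuple[float, ...] = (0.35, 0.35, 0.75)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "saliency" in d and isinstance(d["saliency"], dict):
            d["saliency"] = SaliencyConfig(**d["saliency"])
        if "model" in d and isinstance(d["model"], dict):
            m = dict(d["model"])
            if "input_size" in m:
                m["input_size"] = tuple(m["input_size"])
            d["model"] = VSTConfig(**m)
        if "train" in d and isinstance(d["train"], dict):
            t = dict(d["train"])
            if "aux_loss_weights" in t:
                t["aux_loss_weights"] = tuple(t["aux_loss_weights"])
            d["train"] = TrainConfig(**t)
        if "eval_spacing_mm" in d:
            d["eval_spacing_mm"] = tuple(d["eval_spacing_mm"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
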