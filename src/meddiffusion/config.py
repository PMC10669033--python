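"""Run configuration: one nested, fully serializable description of an
experiment (schedule, model, training, task, data, seed, output)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/latest"
    schedule: dict = field(default_factory=lambda: {
        "T": 2000, "beta_start": 1e-4, "beta_end": 0.02, "sigma_mode": "beta",
    })
    model: dict = field(default_factory=lambda: {
        "base_channels": 16, "channel_mults": [1, 2], "num_groups": 8, "in_channels": 2,
    })
    train: dict = field(default_factory=lambda: {
        "iterations": 200_000, "learning_rate": 1e-4, "batch_size": 8,
        "image_size": 128, "grad_clip": 0.0,
    })
    task: dict = field(default_factory=lambda: {
        "name": "sr", "sr_factor": 4.0, "gauss_sigma": 0.1, "sp_amount": 0.05,
        "mask": {"shape_kind": "rectangles", "count_min": 1, "count_max": 1,
                 "size_min": 0.2, "size_max": 0.4},
    })
    data: dict = field(default_factory=lambda: {
        "kind": "synthetic", "style": "prostate_t2", "n_images": 64,
        "texture_strength": 0.05,
    })

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls()
        out = {}
        for name in ("seed", "out_dir"):
            out[name] = d.get(name, getattr(base, name))
        for name in ("schedule", "model", "train", "task", "data"):
            merged = dict(getattr(base, name))
            merged.update(d.get(name, {}))
            out[name] = merged
        return cls(**out)

    def toy(self) -> "RunConfig":
        """CPU-scale profile: 16x16 images, T=200, ~2k iterations."""
        d = self.to_dict()
        d["schedule"].update({"T": 200})
        d["train"].update({"iterations": 2000, "image_size": 16, "learning_rate": 2e-3})
        d["data"].update({"n_images": 64})
        return RunConfig.from_dict(d)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True, default_flow_style=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return RunConfig.from_dict(data)
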