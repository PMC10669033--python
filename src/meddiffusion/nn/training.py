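"""Training loop for the noise predictor.

Each iteration draws a batch of (x0, y) pairs, per-example timesteps
t ~ U{1..T}, and eps ~ N(0, I), then takes one Adam step on the simplified
noise-matching objective.  Fully reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Sequence

import numpy as np

from ..diffusion import q_sample
from ..schedules import NoiseSchedule
from .unet import UNetNoisePredictor

__all__ = ["TrainConfig", "Adam", "train", "TOY_PROFILE"]


@dataclass
class TrainConfig:
    """Defaults mirror the reference setup (2e5 iterations, lr 1e-4,
    128x128, T=2000); use :data:`TOY_PROFILE` for CPU-scale runs."""

    iterations: int = 200_000
    learning_rate: float = 1e-4
    batch_size: int = 8
    image_size: int = 128
    seed: int = 0
    T: int = 2000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    grad_clip: float = 0.0  # 0 disables
    log_every: int = 50

    def __post_init__(self):
        for name in ("iterations", "learning_rate", "batch_size", "image_size", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


# CPU-scale profile: small enough that train + sample finishes in minutes.
TOY_PROFILE = dict(
    iterations=2000,
    learning_rate=2e-3,
    batch_size=8,
    image_size=16,
    T=200,
)


class Adam:
    """Standard Adam over a named parameter dict, updating in place."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.step_count = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.step_count += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.step_count
        bc2 = 1.0 - b2**self.step_count
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _clip_grads(grads: Dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale


def train(
    model: UNetNoisePredictor,
    dataset: Sequence,
    cfg: TrainConfig,
    s: NoiseSchedule,
    log_fn=None,
) -> tuple[UNetNoisePredictor, list[float]]:
    """Optimize ``model`` in place; returns (model, per-iteration loss history).

    ``dataset`` is a sequence of objects with ``x0`` and ``y`` arrays in
    [-1, 1] (e.g. :class:`~meddiffusion.conditioning.ConditionPair`).
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    if s.T != cfg.T:
        raise ValueError(f"schedule T={s.T} does not match config T={cfg.T}")
    x0s = np.stack([np.asarray(p.x0, dtype=np.float64) for p in dataset])
    ys = np.stack([np.asarray(p.y, dtype=np.float64) for p in dataset])
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    history: list[float] = []
    for it in range(cfg.iterations):
        idx = rng.integers(0, len(dataset), size=cfg.batch_size)
        t = rng.integers(1, cfg.T + 1, size=cfg.batch_size)
        eps = rng.standard_normal((cfg.batch_size,) + x0s.shape[1:])
        xt = q_sample(x0s[idx], t, eps, s)
        loss, grads = model.loss_and_grads(xt, ys[idx], t, eps)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at iteration {it}")
        if cfg.grad_clip > 0:
            _clip_grads(grads, cfg.grad_clip)
        opt.step(grads)
        history.append(loss)
        if log_fn is not None and (it % cfg.log_every == 0 or it == cfg.iterations - 1):
            log_fn({"iter": it, "loss": loss, "t_mean": float(t.mean()), "lr": cfg.learning_rate})
    return model, history
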