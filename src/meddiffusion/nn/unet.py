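"""The conditional noise predictor: abstract contract plus a reference U-Net.

The reference network is an encoder-decoder with skip connections, group
normalization, SiLU activations, and a sinusoidal time embedding injected
into every residual block.  The condition image is channel-concatenated
with the noisy input (in_channels = 2 for single-channel tasks).

The architecture hyperparameters (depth, width, embedding size) are this
artifact's construction; only the U-Net + group-norm skeleton is dictated.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict

import numpy as np

from . import autodiff as ad
from .autodiff import Var

__all__ = [
    "NoisePredictor",
    "UNetNoisePredictor",
    "build_reference_unet",
    "sinusoidal_time_embedding",
    "save_checkpoint",
    "load_checkpoint",
]


class NoisePredictor:
    """Contract: predict(xt, y, t) -> array of xt's shape, never mutating
    inputs, deterministic given weights."""

    def predict(self, xt: np.ndarray, y: np.ndarray, t) -> np.ndarray:
        raise NotImplementedError

    @property
    def parameter_count(self) -> int:
        return 0

    def fingerprint(self) -> str:
        return f"{type(self).__name__}:stateless"


def sinusoidal_time_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Standard transformer-style embedding of integer timesteps; (B, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=1)
    return emb


def _conv_init(rng, cout, cin, k):
    fan_in = cin * k * k
    return rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)


def _linear_init(rng, din, dout):
    return rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)


class UNetNoisePredictor(NoisePredictor):
    """Reference conditional U-Net over (B, C, H, W) float64 arrays.

    Per resolution level one residual block on the way down and one on the
    way up; 2x average-pool / nearest-neighbour resampling between levels;
    a single residual block at the bottleneck.
    """

    def __init__(
        self,
        image_size: int,
        base_channels: int = 16,
        channel_mults: tuple = (1, 2),
        num_groups: int = 8,
        in_channels: int = 2,
        seed: int = 0,
    ):
        levels = len(channel_mults)
        down_factor = 2 ** (levels - 1)
        if image_size % down_factor != 0:
            valid = [down_factor * i for i in range(1, 9)]
            raise ValueError(
                f"image_size {image_size} not divisible by 2^(levels-1)={down_factor}; "
                f"valid sizes include {valid}"
            )
        chs = [base_channels * m for m in channel_mults]
        for c in chs:
            if c % num_groups != 0:
                raise ValueError(f"channels {c} not divisible by num_groups {num_groups}")
        self.image_size = image_size
        self.base_channels = base_channels
        self.channel_mults = tuple(channel_mults)
        self.num_groups = num_groups
        self.in_channels = in_channels
        self.seed = seed
        self.time_dim = 4 * base_channels
        self._chs = chs
        self.params: Dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    # -- parameters --------------------------------------------------------

    def _add_resblock_params(self, rng, name, cin, cout):
        p = self.params
        p[f"{name}.gn1.g"] = np.ones(cin)
        p[f"{name}.gn1.b"] = np.zeros(cin)
        p[f"{name}.conv1.w"] = _conv_init(rng, cout, cin, 3)
        p[f"{name}.conv1.b"] = np.zeros(cout)
        p[f"{name}.temb.w"] = _linear_init(rng, self.time_dim, cout)
        p[f"{name}.temb.b"] = np.zeros(cout)
        p[f"{name}.gn2.g"] = np.ones(cout)
        p[f"{name}.gn2.b"] = np.zeros(cout)
        p[f"{name}.conv2.w"] = _conv_init(rng, cout, cout, 3)
        p[f"{name}.conv2.b"] = np.zeros(cout)
        if cin != cout:
            p[f"{name}.skip.w"] = _conv_init(rng, cout, cin, 1)
            p[f"{name}.skip.b"] = np.zeros(cout)

    def _init_params(self, rng):
        chs = self._chs
        p = self.params
        p["temb1.w"] = _linear_init(rng, self.base_channels, self.time_dim)
        p["temb1.b"] = np.zeros(self.time_dim)
        p["temb2.w"] = _linear_init(rng, self.time_dim, self.time_dim)
        p["temb2.b"] = np.zeros(self.time_dim)
        p["conv_in.w"] = _conv_init(rng, chs[0], self.in_channels, 3)
        p["conv_in.b"] = np.zeros(chs[0])
        prev = chs[0]
        for lvl, ch in enumerate(chs):
            self._add_resblock_params(rng, f"down{lvl}", prev, ch)
            prev = ch
        self._add_resblock_params(rng, "mid", chs[-1], chs[-1])
        cur = chs[-1]
        for lvl in reversed(range(len(chs))):
            cout = chs[lvl - 1] if lvl > 0 else chs[0]
            self._add_resblock_params(rng, f"up{lvl}", cur + chs[lvl], cout)
            cur = cout
        p["gn_out.g"] = np.ones(chs[0])
        p["gn_out.b"] = np.zeros(chs[0])
        # zero-init the output projection: the model starts as the zero predictor
        p["conv_out.w"] = np.zeros((1, chs[0], 3, 3))
        p["conv_out.b"] = np.zeros(1)

    @property
    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.config_dict(), sort_keys=True).encode())
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()[:16]

    def config_dict(self) -> dict:
        return {
            "image_size": self.image_size,
            "base_channels": self.base_channels,
            "channel_mults": list(self.channel_mults),
            "num_groups": self.num_groups,
            "in_channels": self.in_channels,
            "seed": self.seed,
        }

    # -- forward graph -----------------------------------------------------

    def _resblock(self, leaves, name, h: Var, temb: Var, groups: int) -> Var:
        p = leaves
        z = ad.group_norm(h, p[f"{name}.gn1.g"], p[f"{name}.gn1.b"], groups)
        z = ad.conv2d(ad.silu(z), p[f"{name}.conv1.w"], p[f"{name}.conv1.b"])
        tproj = ad.linear(ad.silu(temb), p[f"{name}.temb.w"], p[f"{name}.temb.b"])
        z = ad.add_channel_bias(z, tproj)
        g2 = min(groups, z.shape[1])
        z = ad.group_norm(z, p[f"{name}.gn2.g"], p[f"{name}.gn2.b"], g2)
        z = ad.conv2d(ad.silu(z), p[f"{name}.conv2.w"], p[f"{name}.conv2.b"])
        if f"{name}.skip.w" in p:
            h = ad.conv2d(h, p[f"{name}.skip.w"], p[f"{name}.skip.b"])
        return ad.add(h, z)

    def _forward(self, x: np.ndarray, t: np.ndarray) -> tuple[Var, Dict[str, Var]]:
        """x: (B, in_channels, H, W); t: (B,) integers.  Returns the output
        Var and the leaf Vars (for gradient readout)."""
        leaves = {name: Var(arr) for name, arr in self.params.items()}
        temb0 = sinusoidal_time_embedding(t, self.base_channels)
        temb = ad.linear(Var(temb0), leaves["temb1.w"], leaves["temb1.b"])
        temb = ad.linear(ad.silu(temb), leaves["temb2.w"], leaves["temb2.b"])
        g = self.num_groups
        h = ad.conv2d(Var(x), leaves["conv_in.w"], leaves["conv_in.b"])
        skips = []
        for lvl in range(len(self._chs)):
            gin = min(g, h.shape[1])
            h = self._resblock(leaves, f"down{lvl}", h, temb, gin)
            skips.append(h)
            if lvl < len(self._chs) - 1:
                h = ad.avg_pool2(h)
        h = self._resblock(leaves, "mid", h, temb, min(g, h.shape[1]))
        for lvl in reversed(range(len(self._chs))):
            h = ad.concat_channels(h, skips[lvl])
            h = self._resblock(leaves, f"up{lvl}", h, temb, min(g, h.shape[1]))
            if lvl > 0:
                h = ad.upsample_nearest2(h)
        h = ad.group_norm(h, leaves["gn_out.g"], leaves["gn_out.b"], min(g, h.shape[1]))
        out = ad.conv2d(ad.silu(h), leaves["conv_out.w"], leaves["conv_out.b"])
        return out, leaves

    # -- public API --------------------------------------------------------

    def _to_batch(self, xt, y, t):
        xt = np.asarray(xt, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        squeeze = xt.ndim == 2
        if squeeze:
            xt = xt[None]
            y = y[None]
        t_arr = np.atleast_1d(np.asarray(t, dtype=np.int64))
        if len(t_arr) == 1 and len(xt) > 1:
            t_arr = np.full(len(xt), t_arr[0])
        x = np.stack([xt, y], axis=1)  # (B, 2, H, W)
        return x, t_arr, squeeze

    def predict(self, xt: np.ndarray, y: np.ndarray, t) -> np.ndarray:
        x, t_arr, squeeze = self._to_batch(xt, y, t)
        out, _ = self._forward(x, t_arr)
        result = out.value[:, 0]
        return result[0] if squeeze else result

    def loss_and_grads(
        self, xt: np.ndarray, y: np.ndarray, t: np.ndarray, eps: np.ndarray
    ) -> tuple[float, Dict[str, np.ndarray]]:
        """Mean-square noise-matching loss and its parameter gradients."""
        x, t_arr, _ = self._to_batch(xt, y, t)
        out, leaves = self._forward(x, t_arr)
        target = np.asarray(eps, dtype=np.float64)
        if target.ndim == 2:
            target = target[None]
        loss = ad.mse_loss(out, target[:, None, :, :])
        ad.backward(loss)
        grads = {
            name: (leaf.grad if leaf.grad is not None else np.zeros_like(leaf.value))
            for name, leaf in leaves.items()
        }
        return float(loss.value), grads


def build_reference_unet(
    image_size: int,
    base_channels: int = 16,
    channel_mults: tuple = (1, 2),
    num_groups: int = 8,
    in_channels: int = 2,
    seed: int = 0,
) -> UNetNoisePredictor:
    """Construct the reference conditional U-Net with seeded initialization."""
    return UNetNoisePredictor(
        image_size=image_size,
        base_channels=base_channels,
        channel_mults=channel_mults,
        num_groups=num_groups,
        in_channels=in_channels,
        seed=seed,
    )


def save_checkpoint(path, model: UNetNoisePredictor, schedule_fingerprint: str, extra: dict | None = None):
    """Weights + architecture config + schedule fingerprint in one .npz."""
    meta = {
        "model_config": model.config_dict(),
        "schedule_fingerprint": schedule_fingerprint,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path, expect_schedule_fingerprint: str | None = None):
    """Returns (model, meta).  Refuses to load if the stored schedule
    fingerprint does not match the expected one."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if expect_schedule_fingerprint is not None:
            stored = meta["schedule_fingerprint"]
            if stored != expect_schedule_fingerprint:
                raise ValueError(
                    f"schedule fingerprint mismatch: checkpoint has {stored!r}, "
                    f"expected {expect_schedule_fingerprint!r}"
                )
        model = UNetNoisePredictor(**meta["model_config"])
        for name in model.params:
            model.params[name] = np.asarray(data[name], dtype=np.float64)
    return model, meta
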