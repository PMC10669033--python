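"""Synthetic anatomy-like phantoms.

Piecewise-smooth ellipse phantoms stand in for the three imaging styles so
every pipeline runs without external data: a T2-like style with two nested
zones (a bright core inside a ring) on a body ellipse, an X-ray-like style
with bright lung fields and rib-like bands, and a low-contrast T1-like
style.  Generation is deterministic per (seed, index).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .conditioning import (
    ConditionPair,
    MaskSpec,
    Task,
    make_inpaint_condition,
    make_noise_condition,
    make_sr_condition,
)

__all__ = [
    "PhantomStyle",
    "PhantomSpec",
    "Phantom",
    "generate_phantoms",
    "make_task_dataset",
    "TaskDataset",
    "LABEL_BACKGROUND",
    "LABEL_PZ_RING",
    "LABEL_TZ_CORE",
]

LABEL_BACKGROUND = 0
LABEL_PZ_RING = 1
LABEL_TZ_CORE = 2


class PhantomStyle(str, Enum):
    PROSTATE_T2 = "prostate_t2"
    CHEST_XRAY = "chest_xray"
    PROSTATE_T1 = "prostate_t1"


@dataclass
class PhantomSpec:
    image_size: int = 64
    style: PhantomStyle = PhantomStyle.PROSTATE_T2
    n_images: int = 16
    seed: int = 0
    texture_strength: float = 0.05

    def __post_init__(self):
        self.style = PhantomStyle(self.style)
        if self.image_size < 8:
            raise ValueError(f"image_size must be >= 8, got {self.image_size}")
        if self.n_images < 1:
            raise ValueError(f"n_images must be >= 1, got {self.n_images}")


@dataclass
class Phantom:
    image: np.ndarray  # (H, W) in [-1, 1]
    labels: Optional[np.ndarray]  # (H, W) int zone map, nested-zone style only
    index: int


def _ellipse_mask(size, cy, cx, ry, rx, yy=None, xx=None):
    if yy is None:
        yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _texture(rng, size, strength, smooth=1.5):
    if strength <= 0:
        return np.zeros((size, size))
    noise = rng.standard_normal((size, size))
    return strength * gaussian_filter(noise, smooth)


def _prostate_t2(rng, size, texture_strength):
    # nested zones: bright core (TZ-like) inside a ring (PZ-like) inside a body
    c = size / 2.0
    jit = lambda lo, hi: rng.uniform(lo, hi)
    body_r = jit(0.38, 0.45) * size
    ring_ry = jit(0.20, 0.26) * size
    ring_rx = jit(0.22, 0.30) * size
    core_ry = ring_ry * jit(0.50, 0.62)
    core_rx = ring_rx * jit(0.50, 0.62)
    cy = c + jit(-0.03, 0.03) * size
    cx = c + jit(-0.03, 0.03) * size
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.full((size, size), -0.9)
    body = _ellipse_mask(size, c, c, body_r, body_r * jit(0.9, 1.1), yy, xx)
    ring = _ellipse_mask(size, cy, cx, ring_ry, ring_rx, yy, xx)
    core = _ellipse_mask(size, cy, cx, core_ry, core_rx, yy, xx)
    img[body] = -0.4
    img[ring] = 0.1
    img[core] = 0.55
    labels = np.zeros((size, size), dtype=np.int8)
    labels[ring & ~core] = LABEL_PZ_RING
    labels[core] = LABEL_TZ_CORE
    img = img + _texture(rng, size, texture_strength)
    return np.clip(img, -1.0, 1.0), labels


def _chest_xray(rng, size, texture_strength):
    yy, xx = np.mgrid[0:size, 0:size]
    img = -0.6 + 0.3 * (yy / size)  # vertical gradient background
    c = size / 2.0
    lung_ry = rng.uniform(0.28, 0.34) * size
    lung_rx = rng.uniform(0.14, 0.18) * size
    gap = rng.uniform(0.20, 0.24) * size
    for sign in (-1, 1):
        lung = _ellipse_mask(size, c, c + sign * gap, lung_ry, lung_rx, yy, xx)
        img[lung] = 0.5
        # rib-like periodic horizontal bands inside the lung fields
        period = max(3, int(rng.uniform(0.08, 0.12) * size))
        bands = (yy % period) < max(1, period // 3)
        img[lung & bands] = 0.15
    img = img + _texture(rng, size, texture_strength)
    return np.clip(img, -1.0, 1.0), None


def _prostate_t1(rng, size, texture_strength):
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.full((size, size), -0.35)
    body = _ellipse_mask(
        size, c + rng.uniform(-0.02, 0.02) * size, c + rng.uniform(-0.02, 0.02) * size,
        rng.uniform(0.33, 0.42) * size, rng.uniform(0.33, 0.42) * size, yy, xx,
    )
    img[body] = -0.05  # low soft-tissue contrast
    inner = _ellipse_mask(size, c, c, rng.uniform(0.12, 0.2) * size,
                          rng.uniform(0.12, 0.2) * size, yy, xx)
    img[inner] = 0.1
    img = img + _texture(rng, size, texture_strength)
    return np.clip(img, -1.0, 1.0), None


_STYLE_FNS = {
    PhantomStyle.PROSTATE_T2: _prostate_t2,
    PhantomStyle.CHEST_XRAY: _chest_xray,
    PhantomStyle.PROSTATE_T1: _prostate_t1,
}


def generate_phantoms(spec: PhantomSpec) -> list[Phantom]:
    """Generate ``spec.n_images`` phantoms, bit-reproducible from the spec."""
    out = []
    fn = _STYLE_FNS[spec.style]
    for i in range(spec.n_images):
        rng = np.random.default_rng([spec.seed, i])
        image, labels = fn(rng, spec.image_size, spec.texture_strength)
        out.append(Phantom(image=image, labels=labels, index=i))
    return out


@dataclass
class TaskDataset:
    train: list[ConditionPair]
    val: list[ConditionPair]
    test: list[ConditionPair]
    phantoms: list[Phantom]

    @property
    def all_pairs(self) -> list[ConditionPair]:
        return self.train + self.val + self.test


def _split_indices(n: int) -> tuple[range, range, range]:
    # 80/10/10 by index, with at least one test example when n >= 3
    n_test = max(1, n // 10) if n >= 3 else 0
    n_val = max(1, n // 10) if n >= 3 else 0
    n_train = n - n_val - n_test
    return range(0, n_train), range(n_train, n_train + n_val), range(n_train + n_val, n)


def make_task_dataset(
    spec: PhantomSpec,
    task: Task,
    sr_factor: float = 4.0,
    gauss_sigma: float = 0.1,
    sp_amount: float = 0.05,
    mask_spec: Optional[MaskSpec] = None,
) -> TaskDataset:
    """Compose phantom generation with the matching degradation operator and
    split 80/10/10 by index.

    Per-index seeds make every pair deterministic; inpainting test/val masks
    are fixed per index while training masks vary with the index only through
    the per-index seed (fresh masks per epoch are the caller's choice).
    """
    task = Task(task)
    phantoms = generate_phantoms(spec)
    if mask_spec is None:
        mask_spec = MaskSpec(seed=spec.seed)
    pairs: list[ConditionPair] = []
    for ph in phantoms:
        if task == Task.SR:
            pair = make_sr_condition(ph.image, sr_factor)
        elif task == Task.DENOISE:
            pair = make_noise_condition(
                ph.image, gauss_sigma, sp_amount, seed=spec.seed * 100003 + ph.index
            )
        else:
            idx_spec = MaskSpec(
                shape_kind=mask_spec.shape_kind,
                count_min=mask_spec.count_min,
                count_max=mask_spec.count_max,
                size_min=mask_spec.size_min,
                size_max=mask_spec.size_max,
                seed=mask_spec.seed * 100003 + ph.index,
            )
            pair = make_inpaint_condition(ph.image, idx_spec, train_mode=False)
        pair.meta["index"] = ph.index
        pairs.append(pair)
    tr, va, te = _split_indices(len(pairs))
    return TaskDataset(
        train=[pairs[i] for i in tr],
        val=[pairs[i] for i in va],
        test=[pairs[i] for i in te],
        phantoms=phantoms,
    )
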