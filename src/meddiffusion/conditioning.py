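"""Construction of (target, condition) pairs for the three restoration tasks.

Super-resolution conditions are box-downsampled then bilinearly re-upscaled
versions of the target; denoising conditions add Gaussian plus
salt-and-pepper noise; inpainting conditions zero out randomly placed
rectangles or ellipses.  Group-wise ("patient-wise") min-max normalization
maps raw intensities into [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

__all__ = [
    "Task",
    "ConditionPair",
    "MaskSpec",
    "normalize_patientwise",
    "denormalize",
    "make_sr_condition",
    "make_noise_condition",
    "make_inpaint_condition",
    "SR_FACTORS",
]

# Per-axis downsampling ladder: geometric with ratio sqrt(2), bracketing 4.
SR_FACTORS = {
    "2sqrt2": 2.0 * np.sqrt(2.0),
    "4": 4.0,
    "4sqrt2": 4.0 * np.sqrt(2.0),
    "8": 8.0,
    "8sqrt2": 8.0 * np.sqrt(2.0),
    "16": 16.0,
}


class Task(str, Enum):
    SR = "sr"
    DENOISE = "denoise"
    INPAINT = "inpaint"


@dataclass
class ConditionPair:
    """One training/evaluation example: clean target, degraded condition."""

    x0: np.ndarray
    y: np.ndarray
    task: Task
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x0.shape != self.y.shape:
            raise ValueError(f"x0 shape {self.x0.shape} != y shape {self.y.shape}")
        for name, img in (("x0", self.x0), ("y", self.y)):
            if not np.all(np.isfinite(img)):
                raise ValueError(f"{name} contains non-finite values")
            if img.min() < -1.0 - 1e-9 or img.max() > 1.0 + 1e-9:
                raise ValueError(f"{name} outside [-1, 1]: [{img.min()}, {img.max()}]")
        if self.task == Task.INPAINT:
            if self.mask is None:
                raise ValueError("INPAINT pair requires a mask")
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.x0.shape:
                raise ValueError("mask shape mismatch")
            if not np.array_equal(self.y[~self.mask], self.x0[~self.mask]):
                raise ValueError("INPAINT condition must equal x0 outside the mask")


@dataclass
class MaskSpec:
    """Random occlusion masks: ``count`` shapes with linear sizes drawn as
    fractions of the image side.  Total masked fraction must land in (0, 0.5]."""

    shape_kind: str = "rectangles"  # or "ellipses"
    count_min: int = 1
    count_max: int = 1
    size_min: float = 0.2
    size_max: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.shape_kind not in ("rectangles", "ellipses"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if not (0 < self.size_min <= self.size_max <= 1):
            raise ValueError("need 0 < size_min <= size_max <= 1")
        if not (1 <= self.count_min <= self.count_max):
            raise ValueError("need 1 <= count_min <= count_max")


def normalize_patientwise(group: Sequence[np.ndarray]) -> tuple[list[np.ndarray], tuple[float, float]]:
    """Map a group of images sharing one source linearly into [-1, 1] using
    the group's global min/max.  A constant group maps to all-zeros.

    Returns (normalized images, (group_min, group_max)) so the map inverts.
    """
    if len(group) == 0:
        raise ValueError("empty group")
    arrays = [np.asarray(img, dtype=np.float64) for img in group]
    for img in arrays:
        if not np.all(np.isfinite(img)):
            raise ValueError("non-finite intensities in group")
    mn = min(float(img.min()) for img in arrays)
    mx = max(float(img.max()) for img in arrays)
    if mx == mn:
        return [np.zeros_like(img) for img in arrays], (mn, mx)
    return [(img - mn) / (mx - mn) * 2.0 - 1.0 for img in arrays], (mn, mx)


def denormalize(img: np.ndarray, scale: tuple[float, float]) -> np.ndarray:
    mn, mx = scale
    if mx == mn:
        return np.full_like(np.asarray(img, dtype=np.float64), mn)
    return (np.asarray(img, dtype=np.float64) + 1.0) / 2.0 * (mx - mn) + mn


def _box_downsample(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = img.shape
    if h % out_h == 0 and w % out_w == 0:
        # exact block mean for integer factors
        fh, fw = h // out_h, w // out_w
        return img.reshape(out_h, fh, out_w, fw).mean(axis=(1, 3))
    return resize(img, (out_h, out_w), order=1, anti_aliasing=True, mode="reflect")


def make_sr_condition(x0: np.ndarray, factor: float) -> ConditionPair:
    """Super-resolution condition: box-downsample by ``factor`` per axis,
    then bilinearly upscale back to the original size."""
    x0 = np.asarray(x0, dtype=np.float64)
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    h, w = x0.shape
    out_h = max(1, int(round(h / factor)))
    out_w = max(1, int(round(w / factor)))
    if factor == 1.0:
        y = x0.copy()
    else:
        low = _box_downsample(x0, out_h, out_w)
        y = resize(low, (h, w), order=1, anti_aliasing=False, mode="edge")
    y = np.clip(y, -1.0, 1.0)
    return ConditionPair(
        x0=x0, y=y, task=Task.SR,
        meta={"factor": float(factor), "low_res": (out_h, out_w)},
    )


def make_noise_condition(
    x0: np.ndarray, gauss_sigma: float = 0.1, sp_amount: float = 0.05, seed: int = 0
) -> ConditionPair:
    """Denoising condition: additive Gaussian noise (clipped to [-1, 1]),
    then a fraction of pixels replaced by -1 or +1 with equal probability."""
    x0 = np.asarray(x0, dtype=np.float64)
    if gauss_sigma < 0:
        raise ValueError(f"gauss_sigma must be >= 0, got {gauss_sigma}")
    if not 0 <= sp_amount < 1:
        raise ValueError(f"sp_amount must be in [0, 1), got {sp_amount}")
    rng = np.random.default_rng(seed)
    y = x0.copy()
    if gauss_sigma > 0:
        y = np.clip(y + gauss_sigma * rng.standard_normal(x0.shape), -1.0, 1.0)
    n_replaced = 0
    if sp_amount > 0:
        hit = rng.random(x0.shape) < sp_amount
        salt = rng.random(x0.shape) < 0.5
        y = np.where(hit, np.where(salt, 1.0, -1.0), y)
        n_replaced = int(hit.sum())
    return ConditionPair(
        x0=x0, y=y, task=Task.DENOISE,
        meta={"gauss_sigma": gauss_sigma, "sp_amount": sp_amount, "seed": seed,
              "n_replaced": n_replaced},
    )


def _draw_mask(shape: tuple[int, int], spec: MaskSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    count = int(rng.integers(spec.count_min, spec.count_max + 1))
    for _ in range(count):
        sh = max(1, int(round(rng.uniform(spec.size_min, spec.size_max) * h)))
        sw = max(1, int(round(rng.uniform(spec.size_min, spec.size_max) * w)))
        top = int(rng.integers(0, max(1, h - sh + 1)))
        left = int(rng.integers(0, max(1, w - sw + 1)))
        if spec.shape_kind == "rectangles":
            mask[top : top + sh, left : left + sw] = True
        else:
            cy, cx = top + sh / 2.0, left + sw / 2.0
            yy, xx = np.mgrid[0:h, 0:w]
            mask |= ((yy - cy) / (sh / 2.0)) ** 2 + ((xx - cx) / (sw / 2.0)) ** 2 <= 1.0
    return mask


def make_inpaint_condition(
    x0: np.ndarray,
    spec: MaskSpec,
    train_mode: bool = False,
    rng: Optional[np.random.Generator] = None,
    fill_value: float = 0.0,
) -> ConditionPair:
    """Inpainting condition: masked pixels set to a fill constant (mid-gray).

    Test mode (default) derives the mask deterministically from ``spec.seed``;
    train mode draws a fresh mask from ``rng`` on every call.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    if train_mode:
        if rng is None:
            rng = np.random.default_rng()
    else:
        rng = np.random.default_rng(spec.seed)
    for _attempt in range(10):
        mask = _draw_mask(x0.shape, spec, rng)
        frac = mask.mean()
        if 0.0 < frac <= 0.5:
            break
    else:
        raise RuntimeError("failed to draw a valid mask (fraction in (0, 0.5]) in 10 tries")
    y = np.where(mask, fill_value, x0)
    return ConditionPair(
        x0=x0, y=y, task=Task.INPAINT, mask=mask,
        meta={"masked_fraction": float(frac), "fill_value": fill_value,
              "spec_seed": spec.seed, "train_mode": train_mode},
    )
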