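"""Image-quality measures: accutance (sharpness), Dice overlap, PSNR.

Accutance here is the mean Sobel gradient magnitude over interior pixels of
the [-1, 1] image — a no-reference sharpness proxy.  Absolute accutance
values are only comparable within this artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy.ndimage import convolve

__all__ = ["MetricReport", "accutance", "dice", "psnr", "PSNR_CAP_DB", "evaluate_images"]

PSNR_CAP_DB = 99.0

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


@dataclass
class MetricReport:
    per_image: list[Dict[str, float]]
    aggregate: Dict[str, Dict[str, float]]  # metric -> {"mean", "sd"}
    n: int


def accutance(img: np.ndarray) -> float:
    """Mean 3x3 Sobel gradient magnitude, border pixels excluded."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"need a 2-D image with H, W >= 3, got shape {img.shape}")
    gx = convolve(img, _SOBEL_X, mode="nearest")
    gy = convolve(img, _SOBEL_Y, mode="nearest")
    mag = np.sqrt(gx**2 + gy**2)
    return float(mag[1:-1, 1:-1].mean())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float = 2.0) -> float:
    """10 log10(range^2 / MSE) in dB; identical inputs return the 99 dB cap."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if data_range <= 0:
        raise ValueError(f"data_range must be positive, got {data_range}")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, float(10.0 * np.log10(data_range**2 / mse)))


def evaluate_images(
    preds: Sequence[np.ndarray],
    refs: Sequence[np.ndarray],
    metrics: Sequence[str] = ("accutance", "psnr"),
) -> MetricReport:
    """Per-image and aggregate metrics for paired prediction/reference lists."""
    if len(preds) != len(refs):
        raise ValueError("preds and refs must have equal length")
    fns = {"accutance": lambda p, r: accutance(p), "psnr": lambda p, r: psnr(r, p)}
    per_image = []
    for p, r in zip(preds, refs):
        row = {}
        for m in metrics:
            if m not in fns:
                raise ValueError(f"unknown metric {m!r}")
            row[m] = fns[m](p, r)
        per_image.append(row)
    aggregate = {}
    for m in metrics:
        vals = np.array([row[m] for row in per_image])
        aggregate[m] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return MetricReport(per_image=per_image, aggregate=aggregate, n=len(per_image))
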