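"""Image readers/writers and the [-1, 1] <-> 8-bit mapping.

8-bit value v maps to v/127.5 - 1 (so the quantization bin half-width is
1/255, matching the discretized decoder's delta); writing inverts with
round((x + 1) * 127.5).  NIfTI volumes are normalized group-wise over the
whole volume before a slice is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .conditioning import normalize_patientwise
from .diffusion import validate_image

__all__ = ["ImageMeta", "read_image", "write_image", "to_uint8", "from_uint8"]


@dataclass
class ImageMeta:
    source: str
    kind: str  # "png" | "nifti"
    scale: tuple = (0.0, 255.0)
    extra: dict = field(default_factory=dict)


def from_uint8(v: np.ndarray) -> np.ndarray:
    return np.asarray(v, dtype=np.float64) / 127.5 - 1.0


def to_uint8(x: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=np.float64), -1.0, 1.0)
    return np.round((x + 1.0) * 127.5).astype(np.uint8)


def read_image(path, slice_index: int = 0, target_size: int | None = None) -> tuple[np.ndarray, ImageMeta]:
    """Read a grayscale PNG (8-bit) or a NIfTI slice into [-1, 1].

    ``target_size`` resizes (bilinear, anti-aliased) to a square image.
    """
    img, meta = _read_image_raw(Path(path), slice_index)
    if target_size is not None and img.shape != (target_size, target_size):
        from skimage.transform import resize

        meta.extra["resized_from"] = list(map(int, img.shape))
        img = np.clip(
            resize(img, (target_size, target_size), order=1, anti_aliasing=True,
                   mode="reflect"),
            -1.0, 1.0,
        )
    return img, meta


def _read_image_raw(path: Path, slice_index: int) -> tuple[np.ndarray, ImageMeta]:
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        if vol.ndim == 2:
            vol = vol[..., None]
        if not 0 <= slice_index < vol.shape[-1]:
            raise ValueError(f"slice_index {slice_index} outside 0..{vol.shape[-1] - 1}")
        slices = [vol[..., i] for i in range(vol.shape[-1])]
        normed, scale = normalize_patientwise(slices)
        img = normed[slice_index]
        meta = ImageMeta(source=str(path), kind="nifti", scale=scale,
                         extra={"slice_index": slice_index, "n_slices": vol.shape[-1]})
        return validate_image(img), meta
    if path.suffix.lower() in (".png", ".pgm"):
        with Image.open(path) as im:
            if im.mode not in ("L", "I;16", "I"):
                im = im.convert("L")
            arr = np.asarray(im)
        if arr.dtype != np.uint8:
            raise ValueError(f"only 8-bit grayscale PNG supported, got dtype {arr.dtype}")
        img = from_uint8(arr)
        return validate_image(img), ImageMeta(source=str(path), kind="png")
    raise ValueError(f"unsupported image format: {path.name!r} (use PNG or NIfTI)")


def write_image(path, img: np.ndarray) -> None:
    """Write a [-1, 1] image as 8-bit grayscale PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(to_uint8(np.asarray(img)), mode="L").save(path)
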