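"""Four-step fundus preprocessing: resize, augmentation, median filter, unsharp mask.

All operations accept either a raw ``numpy`` array or an :class:`Image`
wrapper; pipelines use the wrapper so every applied step is recorded in the
image's op log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import transform

LUMA_WEIGHTS = (0.299, 0.587, 0.114)

AUGMENT_OPS = ("rot90", "rot180", "rot270", "hflip", "vflip", "small_rotation")


@dataclass
class Image:
    """Intensity raster in [0, 255] with provenance metadata and an op log."""

    pixels: np.ndarray
    grade: int | None = None
    source: str | None = None
    ops: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3) or 0 in self.pixels.shape:
            raise ValueError(f"invalid image shape {self.pixels.shape}")


@dataclass
class PreprocessConfig:
    target_size: int = 512
    median_kernel: int = 3
    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0
    augmentation: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")
        if self.unsharp_amount < 0:
            raise ValueError("unsharp_amount must be >= 0")
        for op in self.augmentation:
            if op not in AUGMENT_OPS:
                raise ValueError(f"unknown augmentation op {op!r}; valid: {AUGMENT_OPS}")


def _pixels(img: Image | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, Image) else np.asarray(img)


def _rewrap(img: Image | np.ndarray, pixels: np.ndarray, op: str):
    if isinstance(img, Image):
        return Image(pixels, grade=img.grade, source=img.source, ops=img.ops + [op])
    return pixels


def to_grayscale(img: Image | np.ndarray) -> np.ndarray:
    """Luminance conversion (0.299 R + 0.587 G + 0.114 B), float output."""
    px = _pixels(img).astype(float)
    if px.ndim == 2:
        return px
    return px @ np.asarray(LUMA_WEIGHTS)


def resize_image(img: Image | np.ndarray, target: int):
    """Rescale to ``target x target`` (per channel); no cropping.

    Bilinear interpolation with anti-aliasing when shrinking; an input already
    at the target size is returned pixel-identical.
    """
    px = _pixels(img)
    if px.size == 0:
        raise ValueError("empty image")
    if px.shape[0] == target and px.shape[1] == target:
        return _rewrap(img, px.copy(), f"resize:{target}")
    shape = (target, target) + px.shape[2:]
    shrinking = px.shape[0] > target or px.shape[1] > target
    out = transform.resize(
        px.astype(float), shape, order=1, preserve_range=True, anti_aliasing=shrinking
    )
    out = np.clip(out, 0, 255)
    if np.issubdtype(px.dtype, np.integer):
        out = np.rint(out).astype(px.dtype)
    return _rewrap(img, out, f"resize:{target}")


def augment(img: Image | np.ndarray, ops: Sequence[str], seed: int = 0) -> list:
    """Apply each label-preserving op independently; one output per op.

    ``small_rotation`` draws its angle uniformly from +/-15 degrees using
    ``seed``; all other ops are deterministic index maps.
    """
    px = _pixels(img)
    rng = np.random.default_rng(seed)
    outputs = []
    for op in ops:
        if op == "rot90":
            out = np.rot90(px, 1)
        elif op == "rot180":
            out = np.rot90(px, 2)
        elif op == "rot270":
            out = np.rot90(px, 3)
        elif op == "hflip":
            out = px[:, ::-1]
        elif op == "vflip":
            out = px[::-1, :]
        elif op == "small_rotation":
            angle = rng.uniform(-15, 15)
            out = transform.rotate(px.astype(float), angle, preserve_range=True, order=1)
            out = np.clip(out, 0, 255)
            if np.issubdtype(px.dtype, np.integer):
                out = np.rint(out).astype(px.dtype)
        else:
            raise ValueError(f"unknown augmentation op {op!r}; valid: {AUGMENT_OPS}")
        outputs.append(_rewrap(img, np.ascontiguousarray(out), f"augment:{op}"))
    return outputs


def median_filter(img: Image | np.ndarray, kernel: int = 3):
    """Per-channel median with reflect padding; output range within input range."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("median kernel must be odd and >= 3")
    px = _pixels(img)
    if px.ndim == 2:
        out = ndimage.median_filter(px, size=kernel, mode="reflect")
    else:
        out = np.stack(
            [ndimage.median_filter(px[..., c], size=kernel, mode="reflect") for c in range(px.shape[2])],
            axis=-1,
        )
    return _rewrap(img, out, f"median:{kernel}")


def unsharp_mask(img: Image | np.ndarray, radius: float = 2.0, amount: float = 1.0):
    """Sharpen by adding back the difference from a Gaussian-blurred copy.

    ``out = clip(img + amount * (img - blur(img, radius)), 0, 255)``;
    ``amount=0`` returns the input bit-exactly.
    """
    if amount < 0:
        raise ValueError("amount must be >= 0")
    px = _pixels(img)
    if amount == 0:
        return _rewrap(img, px.copy(), "unsharp:identity")
    pxf = px.astype(float)
    sigma = (radius, radius) if pxf.ndim == 2 else (radius, radius, 0)
    blurred = ndimage.gaussian_filter(pxf, sigma=sigma)
    out = np.clip(pxf + amount * (pxf - blurred), 0, 255)
    if np.issubdtype(px.dtype, np.integer):
        out = np.rint(out).astype(px.dtype)
    return _rewrap(img, out, f"unsharp:{radius}:{amount}")


def preprocess_pipeline(img: Image | np.ndarray, cfg: PreprocessConfig) -> Image:
    """Resize -> median filter -> unsharp mask, logging each step.

    Augmentation is a dataset-level balancing step and is applied by the
    pipeline orchestrator, not per image here.
    """
    if not isinstance(img, Image):
        img = Image(np.asarray(img))
    img = resize_image(img, cfg.target_size)
    img = median_filter(img, cfg.median_kernel)
    img = unsharp_mask(img, cfg.unsharp_radius, cfg.unsharp_amount)
    return img
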