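"""Seeded generator of graded fundus-like images with ground-truth lesion inventories.

Emulates, at small scale, a five-grade diabetic-retinopathy fundus dataset:
a circular field of view on black background, a bright elliptical optic disc,
a branching dark vessel tree, and grade-dependent counts of dark
microaneurysms, dark hemorrhage blobs, bright exudates and bright blurred
cotton-wool spots, plus Gaussian and salt/pepper noise. Ground truth (lesion
type, center, radius, contrast sign) is returned with every image so tests can
assert against construction rather than against a model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

LESION_TYPES = ("microaneurysm", "hemorrhage", "exudate", "cotton_wool")

#: radius ranges (pixels) per lesion type at the reference 256 px image size;
#: ranges are kept narrow so lesion area scales with lesion count and grades
#: stay separable by area statistics
LESION_RADII = {
    "microaneurysm": (1.5, 2.5),
    "hemorrhage": (5, 8),
    "exudate": (4, 6),
    "cotton_wool": (6, 8),
}

LESION_SIGN = {
    "microaneurysm": "dark",
    "hemorrhage": "dark",
    "exudate": "bright",
    "cotton_wool": "bright",
}

#: per-grade (lo, hi) inclusive count ranges; expected counts strictly
#: increase with grade for every type so grades are separable by lesion-area
#: statistics by construction.
DEFAULT_GRADE_TABLE: dict[int, dict[str, tuple[int, int]]] = {
    0: {"microaneurysm": (0, 0), "hemorrhage": (0, 0), "exudate": (0, 0), "cotton_wool": (0, 0)},
    1: {"microaneurysm": (2, 3), "hemorrhage": (1, 1), "exudate": (1, 1), "cotton_wool": (0, 0)},
    2: {"microaneurysm": (6, 8), "hemorrhage": (3, 4), "exudate": (3, 4), "cotton_wool": (1, 1)},
    3: {"microaneurysm": (12, 15), "hemorrhage": (6, 8), "exudate": (6, 8), "cotton_wool": (2, 2)},
    4: {"microaneurysm": (20, 24), "hemorrhage": (10, 12), "exudate": (10, 12), "cotton_wool": (4, 4)},
}


@dataclass
class Lesion:
    kind: str
    center: tuple[int, int]  # (row, col)
    radius: float
    contrast: str  # "dark" | "bright"


@dataclass
class LesionInventory:
    lesions: list[Lesion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def count(self, kind: str) -> int:
        return sum(1 for l in self.lesions if l.kind == kind)


@dataclass
class FundusConfig:
    """Generator parameters.

    ``grade_lesion_table`` maps grade -> lesion type -> inclusive (lo, hi)
    count range. Grade 0 must be lesion-free and expected counts must be
    non-decreasing in grade for every type.
    """

    image_size: int = 256
    field_radius_frac: float = 0.95
    grade_lesion_table: dict[int, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GRADE_TABLE.items()}
    )
    noise_gaussian_sigma: float = 4.0
    impulse_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0 < self.field_radius_frac <= 1:
            raise ValueError("field_radius_frac must be in (0, 1]")
        if self.noise_gaussian_sigma < 0 or not 0 <= self.impulse_fraction < 1:
            raise ValueError("invalid noise parameters")
        table = self.grade_lesion_table
        if sorted(table) != [0, 1, 2, 3, 4]:
            raise ValueError("grade_lesion_table must cover grades 0..4")
        for kind in LESION_TYPES:
            prev_mean = -1.0
            for g in range(5):
                lo, hi = table[g].get(kind, (0, 0))
                if lo < 0 or hi < lo:
                    raise ValueError(f"invalid count range for {kind} at grade {g}")
                if g == 0 and hi != 0:
                    raise ValueError("grade 0 must be lesion-free")
                mean = (lo + hi) / 2
                if mean < prev_mean:
                    raise ValueError(f"expected {kind} count decreases at grade {g}")
                prev_mean = mean


def _field_mask(size: int, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def _draw_disk(img: np.ndarray, center: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _render_background(size: int, field: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Orange-red retinal ground with a soft radial falloff."""
    rr, cc = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    d = np.sqrt((rr - c) ** 2 + (cc - c) ** 2) / (size / 2)
    falloff = 1.0 - 0.35 * d**2
    base = np.zeros((size, size, 3), dtype=float)
    tint = np.array([185.0, 95.0, 45.0]) * (0.95 + 0.1 * rng.random())
    # low-frequency mottle so the field is not flat
    coarse = rng.normal(0, 1, (8, 8))
    mottle = np.kron(coarse, np.ones((size // 8, size // 8)))[:size, :size]
    for ch in range(3):
        base[..., ch] = tint[ch] * falloff * (1 + 0.04 * mottle)
    base[~field] = 0.0
    return base


def _render_optic_disc(img: np.ndarray, field_radius: float, rng: np.random.Generator) -> tuple[int, int]:
    size = img.shape[0]
    c = (size - 1) / 2
    ang = rng.uniform(0, 2 * math.pi)
    rho = rng.uniform(0.35, 0.6) * field_radius
    dr, dc = int(c + rho * math.sin(ang)), int(c + rho * math.cos(ang))
    a = field_radius * rng.uniform(0.13, 0.15)  # semi-axes
    b = a * rng.uniform(0.8, 1.0)
    rr, cc = np.mgrid[0:size, 0:size]
    inside = ((rr - dr) / a) ** 2 + ((cc - dc) / b) ** 2 <= 1.0
    img[inside] = 0.3 * img[inside] + 0.7 * np.array([235.0, 215.0, 160.0])
    return dr, dc


def _render_vessels(
    img: np.ndarray, origin: tuple[int, int], field: np.ndarray, rng: np.random.Generator
) -> None:
    """Branching dark random-walk curves emanating from the optic disc."""
    size = img.shape[0]
    n_primary = 5  # fixed count keeps total vessel area comparable across images
    stack = [
        (float(origin[0]), float(origin[1]), rng.uniform(0, 2 * math.pi), size * 0.55, 2.0)
        for _ in range(n_primary)
    ]
    dark = np.array([0.45, 0.35, 0.35])
    while stack:
        r, cpos, ang, length, width = stack.pop()
        steps = int(length)
        for _ in range(steps):
            ang += rng.normal(0, 0.15)
            r += math.sin(ang)
            cpos += math.cos(ang)
            ir, ic = int(round(r)), int(round(cpos))
            w = max(1, int(round(width)))
            if not (0 <= ir < size and 0 <= ic < size) or not field[ir, ic]:
                break
            sl = (slice(max(0, ir - w), ir + w + 1), slice(max(0, ic - w), ic + w + 1))
            img[sl] = img[sl] * dark
            if width > 1 and rng.random() < 0.015:  # branch
                stack.append((r, cpos, ang + rng.uniform(-1.0, 1.0), length * 0.5, width * 0.7))


def _render_lesion(img: np.ndarray, lesion: Lesion, rng: np.random.Generator) -> None:
    size = img.shape[0]
    rr, cc = np.mgrid[0:size, 0:size]
    dist2 = (rr - lesion.center[0]) ** 2 + (cc - lesion.center[1]) ** 2
    if lesion.kind == "hemorrhage":
        # irregular blob: radius modulated by angle
        ang = np.arctan2(rr - lesion.center[0], cc - lesion.center[1])
        k = rng.integers(2, 5)
        phase = rng.uniform(0, 2 * math.pi)
        wobble = 1 + 0.3 * np.sin(k * ang + phase)
        inside = dist2 <= (lesion.radius * wobble) ** 2
    else:
        inside = dist2 <= lesion.radius**2
    if lesion.contrast == "dark":
        img[inside] *= 0.30  # darker than vessels, so lesion area is identifiable
    else:
        target = np.array([238.0, 228.0, 185.0])
        if lesion.kind == "cotton_wool":
            # soft edge: blend weight decays with distance
            w = np.clip(1.2 - np.sqrt(dist2) / lesion.radius, 0, 1)[..., None] * 0.8
            img[:] = img * (1 - w) + target * w
            return
        img[inside] = 0.15 * img[inside] + 0.85 * target


def generate_fundus(
    config: FundusConfig, grade: int, seed: int
) -> tuple[np.ndarray, LesionInventory]:
    """Render one synthetic fundus image for a DR grade in 0..4.

    Returns an ``(H, W, 3)`` uint8 image (black outside the circular field)
    and the exact inventory of rendered lesions. Bit-identical for identical
    ``(config, grade, seed)``.
    """
    if not isinstance(grade, (int, np.integer)) or not 0 <= grade <= 4:
        raise ValueError(f"grade must be an integer in 0..4, got {grade!r}")
    rng = np.random.default_rng(seed)
    size = config.image_size
    field_radius = config.field_radius_frac * size / 2
    field = _field_mask(size, field_radius)

    img = _render_background(size, field, rng)
    disc = _render_optic_disc(img, field_radius, rng)
    _render_vessels(img, disc, field, rng)
    clean_gray = img.mean(axis=2)  # noise-free anatomy, used to site lesions

    # noise first, lesions on top: lesion interiors stay clean ground truth
    if config.noise_gaussian_sigma > 0:
        img[field] += rng.normal(0, config.noise_gaussian_sigma, (int(field.sum()), 3))
    if config.impulse_fraction > 0:
        flat_idx = np.flatnonzero(field)
        n_imp = int(round(config.impulse_fraction * flat_idx.size))
        if n_imp:
            hit = rng.choice(flat_idx, size=n_imp, replace=False)
            vals = np.where(rng.random(n_imp) < 0.5, 0.0, 255.0)
            img.reshape(-1, 3)[hit] = vals[:, None]

    scale = size / 256.0  # lesion radii are defined at the 256 px reference
    inventory = LesionInventory()
    c = (size - 1) / 2
    # lesions are placed on clean background, away from vessels, the optic
    # disc and each other, so every lesion's contrast sign is guaranteed
    gray = clean_gray
    ref = float(np.median(gray[field]))
    placed: list[tuple[int, int, float]] = []

    def neighborhood(cand: tuple[int, int], reach: float) -> np.ndarray:
        w = int(math.ceil(reach))
        r0, r1 = max(0, cand[0] - w), min(size, cand[0] + w + 1)
        c0, c1 = max(0, cand[1] - w), min(size, cand[1] + w + 1)
        sub = gray[r0:r1, c0:c1]
        dr, dc = np.mgrid[r0:r1, c0:c1]
        return sub[np.hypot(dr - cand[0], dc - cand[1]) <= reach]
    for kind in LESION_TYPES:
        lo, hi = config.grade_lesion_table[grade].get(kind, (0, 0))
        n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        rlo, rhi = LESION_RADII[kind]
        for _ in range(n):
            radius = rng.uniform(rlo, rhi) * scale
            center = None
            fallback, fallback_sep = None, -1.0
            for _try in range(300):
                max_rho = field_radius - radius - 1
                rho = math.sqrt(rng.random()) * max_rho
                ang = rng.uniform(0, 2 * math.pi)
                cand = (int(round(c + rho * math.sin(ang))), int(round(c + rho * math.cos(ang))))
                patch = neighborhood(cand, 1.6 * radius + 4)
                clean = patch.size and 0.6 * ref <= patch.mean() <= 1.25 * ref and patch.min() >= 0.35 * ref
                if not clean:
                    continue
                sep = min(
                    (math.hypot(cand[0] - pr, cand[1] - pc) - 1.4 * prad for pr, pc, prad in placed),
                    default=math.inf,
                )
                if sep >= 1.6 * radius + 6:
                    center = cand
                    break
                if sep > fallback_sep:  # crowded field: remember the best-spread spot
                    fallback, fallback_sep = cand, sep
            if center is None:
                center = fallback if fallback is not None else cand
            lesion = Lesion(kind, center, radius, LESION_SIGN[kind])
            _render_lesion(img, lesion, rng)
            inventory.lesions.append(lesion)
            placed.append((center[0], center[1], radius))

    img = np.clip(img, 0, 255)
    img[~field] = 0
    return img.astype(np.uint8), inventory


def _image_seed(seed: int, grade: int, index: int) -> int:
    """Stable per-image child seed below 2**31."""
    return int(np.random.default_rng([seed, grade, index]).integers(2**31))


def generate_dataset(
    config: FundusConfig,
    n_per_class: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame, list[LesionInventory]]:
    """Generate a balanced 5-grade dataset of ``5 * n_per_class`` images.

    Returns images (grade-major order), a manifest DataFrame with columns
    ``path, grade, seed``, and the per-image inventories. If ``out_dir`` is
    given, PNGs and ``manifest.csv`` are written there.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images: list[np.ndarray] = []
    inventories: list[LesionInventory] = []
    rows = []
    for grade in range(5):
        for i in range(n_per_class):
            s = _image_seed(seed, grade, i)
            img, inv = generate_fundus(config, grade, s)
            images.append(img)
            inventories.append(inv)
            rows.append({"path": f"grade{grade}_{i:04d}.png", "grade": grade, "seed": s})
    manifest = pd.DataFrame(rows, columns=["path", "grade", "seed"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, rows):
            PILImage.fromarray(img).save(out / row["path"])
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, manifest, inventories
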