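"""Uniform local binary pattern (LBP) texture histograms.

For each interior pixel, the T=8 circular neighbors are thresholded against
the center (ties count as 1) and packed into an 8-bit code with weights 2^i.
Codes with at most two circular 0<->1 transitions are "uniform"; with T=8
there are 58 of them, and all remaining codes pool into one catch-all bin, so
each image yields a normalized 59-bin histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix
from .preprocessing import Image, to_grayscale

#: counter-clockwise square-ring offsets (row, col) for R=1, starting east;
#: row axis points down, so negative row offsets are "up".
_SQUARE_RING = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


@dataclass
class LBPConfig:
    T: int = 8
    R: int = 1
    mapping: str = "uniform-59"

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.mapping == "uniform-59" and self.T != 8:
            raise ValueError("uniform-59 mapping requires T=8 (58 uniform patterns + 1 bin)")


def circular_transitions(code: int, bits: int = 8) -> int:
    """Number of 0<->1 transitions around the circular bit string of ``code``."""
    rotated = ((code >> 1) | ((code & 1) << (bits - 1))) & ((1 << bits) - 1)
    return bin(code ^ rotated).count("1")


def uniform_bin_table(bits: int = 8) -> np.ndarray:
    """Map each code 0..2^bits-1 to its histogram bin.

    Uniform codes (<= 2 transitions) get bins 0..57 in increasing code order;
    every non-uniform code maps to the final catch-all bin 58.
    """
    codes = np.arange(1 << bits)
    uniform = np.array([circular_transitions(int(c), bits) <= 2 for c in codes])
    table = np.full(1 << bits, int(uniform.sum()), dtype=int)
    table[uniform] = np.arange(int(uniform.sum()))
    return table


def neighbor_offsets(T: int, R: int) -> list[tuple[float, float]]:
    """Sampling offsets (drow, dcol) ordered counter-clockwise starting east.

    For the classic (T=8, integer R) configuration the square ring of the
    3x3 (or (2R+1)^2) neighborhood is used; otherwise points lie on the
    circle of radius R and are bilinearly interpolated.
    """
    if T == 8 and float(R).is_integer():
        return [(dr * int(R), dc * int(R)) for dr, dc in _SQUARE_RING]
    angles = 2 * np.pi * np.arange(T) / T
    return [(-R * np.sin(a), R * np.cos(a)) for a in angles]


def lbp_code(center: float, neighbors, T: int = 8) -> int:
    """Pack threshold bits into a code: bit i = 1 iff neighbor_i >= center.

    ``neighbors`` must hold exactly ``T`` intensities in counter-clockwise
    order; ties with the center count as 1.
    """
    neighbors = np.asarray(neighbors, dtype=float)
    if neighbors.ndim != 1 or neighbors.size != T:
        raise ValueError(f"expected exactly {T} neighbor values, got shape {neighbors.shape}")
    bits = neighbors >= center
    return int(np.sum(bits * (1 << np.arange(T))))


def _sample_plane(gray: np.ndarray, dr: float, dc: float, R: int) -> np.ndarray:
    """Neighbor intensities for every interior pixel, bilinear off-grid."""
    H, W = gray.shape
    rows = np.arange(R, H - R)
    cols = np.arange(R, W - R)
    if float(dr).is_integer() and float(dc).is_integer():
        return gray[int(R + dr) : int(H - R + dr), int(R + dc) : int(W - R + dc)]
    rr = rows[:, None] + dr
    cc = cols[None, :] + dc
    r0, c0 = np.floor(rr).astype(int), np.floor(cc).astype(int)
    fr, fc = rr - r0, cc - c0
    g = gray
    return (
        g[r0, c0] * (1 - fr) * (1 - fc)
        + g[r0, c0 + 1] * (1 - fr) * fc
        + g[r0 + 1, c0] * fr * (1 - fc)
        + g[r0 + 1, c0 + 1] * fr * fc
    )


def lbp_code_map(gray: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Per-pixel LBP codes for all interior pixels (border of width R excluded)."""
    cfg = cfg or LBPConfig()
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("LBP input must be single-channel; convert to grayscale first")
    R = cfg.R
    if min(gray.shape) <= 2 * R:
        raise ValueError(f"image sides must exceed 2R={2 * R}")
    center = gray[R:-R, R:-R]
    codes = np.zeros(center.shape, dtype=int)
    for i, (dr, dc) in enumerate(neighbor_offsets(cfg.T, R)):
        codes |= (_sample_plane(gray, dr, dc, R) >= center).astype(int) << i
    return codes


def lbp_histogram(img, cfg: LBPConfig | None = None) -> np.ndarray:
    """Normalized 59-bin uniform-pattern histogram of a grayscale image."""
    cfg = cfg or LBPConfig()
    px = img.pixels if isinstance(img, Image) else np.asarray(img)
    if px.ndim != 2:
        raise ValueError("LBP input must be single-channel; convert to grayscale first")
    codes = lbp_code_map(px, cfg)
    table = uniform_bin_table(cfg.T)
    n_bins = int(table.max()) + 1  # 59 for T=8
    hist = np.bincount(table[codes.ravel()], minlength=n_bins).astype(float)
    return hist / hist.sum()


def extract_lbp_features(images, cfg: LBPConfig | None = None) -> FeatureMatrix:
    """Stack per-image LBP histograms into an N x 59 block tagged ``lbp``.

    RGB inputs are converted by the standard luminance weights first.
    """
    images = list(images)
    if not images:
        raise ValueError("no images given")
    rows = []
    for img in images:
        px = img.pixels if isinstance(img, Image) else np.asarray(img)
        gray = to_grayscale(px) if px.ndim == 3 else px
        rows.append(lbp_histogram(gray, cfg))
    values = np.vstack(rows)
    return FeatureMatrix(values, ["lbp"] * values.shape[1])
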