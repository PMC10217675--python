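"""Feature-block fusion and optimizer-mask application.

The deep ensemble ``E = [graphnet | resnet]`` is optimized by the swarm
algorithms; applying the resulting mask in ``zero`` mode preserves the
printed matrix width (deselected columns are zeroed), while ``drop`` mode
removes them. The final classifier input is the LBP block concatenated with
the masked deep ensemble.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureMatrix, hstack_matrices


def fuse_blocks(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation preserving block tags; rows must align."""
    if not blocks:
        raise ValueError("no blocks to fuse")
    n = blocks[0].n
    for j, b in enumerate(blocks):
        if b.n != n:
            raise ValueError(
                f"block {j} ({b.block_tags[0] if b.block_tags else '?'}) has {b.n} rows, expected {n}"
            )
    if len(blocks) == 1:
        return blocks[0]
    return hstack_matrices(blocks)


def apply_mask(matrix: FeatureMatrix, mask, mode: str = "zero") -> FeatureMatrix:
    """Apply a selection bit mask to the columns of a feature matrix.

    ``drop``: keep only selected columns (width = popcount). ``zero``: width
    unchanged, deselected columns set to 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != matrix.width:
        raise ValueError(f"mask length {mask.size} != matrix width {matrix.width}")
    if mode == "drop":
        return matrix.select_columns(np.flatnonzero(mask))
    if mode == "zero":
        values = matrix.values.copy()
        values[:, ~mask] = 0.0
        return FeatureMatrix(values, list(matrix.block_tags), matrix.row_ids)
    raise ValueError(f"unknown mode {mode!r}; use 'drop' or 'zero'")


def build_final_vector(
    lbp_selected: FeatureMatrix,
    deep_fused: FeatureMatrix,
    optimizer_mask,
    mode: str = "zero",
) -> FeatureMatrix:
    """Final classifier input: [LBP block | masked deep ensemble].

    The LBP block is exempt from swarm optimization; in the default ``zero``
    mode the final width is always l + g + r.
    """
    if lbp_selected.width == 0:
        raise ValueError("LBP block must be non-empty")
    return fuse_blocks([lbp_selected, apply_mask(deep_fused, optimizer_mask, mode)])
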