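"""N x D feature matrices with named column blocks and plain-text persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_BLOCKS = ("lbp", "graphnet", "resnet", "fused")


@dataclass
class FeatureMatrix:
    """Real-valued feature matrix with a block tag per column.

    Parameters
    ----------
    values : (N, D) float array; must be finite.
    block_tags : length-D sequence of tags (e.g. ``"lbp"``, ``"graphnet"``,
        ``"resnet"``) partitioning the columns into named blocks.
    row_ids : optional length-N identifiers (image paths or indices).
    """

    values: np.ndarray
    block_tags: list[str] = field(default_factory=list)
    row_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN or Inf")
        if not self.block_tags:
            self.block_tags = ["fused"] * self.values.shape[1]
        self.block_tags = [str(t) for t in self.block_tags]
        if len(self.block_tags) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.block_tags)} block tags for {self.values.shape[1]} columns"
            )
        if self.row_ids is not None and len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length does not match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def block_widths(self) -> dict[str, int]:
        widths: dict[str, int] = {}
        for t in self.block_tags:
            widths[t] = widths.get(t, 0) + 1
        return widths

    def block(self, tag: str) -> "FeatureMatrix":
        """Extract the sub-matrix of one column block (column order preserved)."""
        idx = [i for i, t in enumerate(self.block_tags) if t == tag]
        if not idx:
            raise KeyError(f"no columns tagged {tag!r}; present: {sorted(set(self.block_tags))}")
        return FeatureMatrix(self.values[:, idx], [tag] * len(idx), self.row_ids)

    def select_columns(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            self.values[:, idx], [self.block_tags[i] for i in idx], self.row_ids
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with ``block:index`` column headers."""
        cols = [f"{t}:{i}" for i, t in enumerate(self.block_tags)]
        df = pd.DataFrame(self.values, columns=cols)
        if self.row_ids is not None:
            df.insert(0, "row_id", self.row_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        row_ids = None
        if "row_id" in df.columns:
            row_ids = df.pop("row_id").astype(str).tolist()
        tags = [c.split(":", 1)[0] for c in df.columns]
        return cls(df.to_numpy(dtype=float), tags, row_ids)

    def to_npz(self, path: str | Path) -> None:
        """Write as a compressed array with a JSON sidecar carrying block tags."""
        path = Path(path)
        np.savez_compressed(path, values=self.values)
        sidecar = {"block_tags": self.block_tags, "row_ids": self.row_ids}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_npz(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        values = np.load(path)["values"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values, meta["block_tags"], meta["row_ids"])


def hstack_matrices(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation; rows must agree in count and order."""
    if not blocks:
        raise ValueError("no blocks to stack")
    n = blocks[0].n
    for j, b in enumerate(blocks):
        if b.n != n:
            raise ValueError(f"block {j} has {b.n} rows, expected {n}")
    values = np.hstack([b.values for b in blocks])
    tags = [t for b in blocks for t in b.block_tags]
    return FeatureMatrix(values, tags, blocks[0].row_ids)
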