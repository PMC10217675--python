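"""Shannon-entropy feature scoring and selection.

Each feature is scored by how concentrated its per-class mass is. Columns are
min-max normalized to [0,1]; the class mass o_ik of feature i in class k is
the sum of normalized values over that class's samples; relative frequencies
rf_ik = o_ik / sum_k o_ik form a distribution over the t classes whose Shannon
entropy E(r_i) = -sum_k rf_ik log2 rf_ik lies in [0, log2 t]. The selection
score is log2(t) - E(r_i): 0 for a feature spread uniformly over classes,
log2(t) for one concentrated in a single class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .features import FeatureMatrix


@dataclass
class EntropyProfile:
    entropy: np.ndarray  # E(r_i) in bits, per feature
    score: np.ndarray  # log2(t) - E(r_i)
    t: int  # number of classes
    o: np.ndarray  # (D, t) class-mass table o_ik
    rf: np.ndarray  # (D, t) normalized frequencies
    mode: str = "mass"


@dataclass
class SelectionResult:
    mask: np.ndarray  # boolean, length D
    ranked: np.ndarray  # all feature indices, best score first
    k: int
    criterion: str
    error: float | None = None
    warning: bool = False
    rounds: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if int(self.mask.sum()) != self.k:
            raise ValueError("popcount(mask) must equal k")

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=0)
    rng = values.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (values - lo) / rng


def feature_entropy(
    features: FeatureMatrix | np.ndarray,
    labels,
    mode: str = "mass",
    bins: int = 10,
) -> EntropyProfile:
    """Per-feature class entropy and selection score.

    ``mode='mass'`` (default) sums min-max-normalized feature values per
    class; ``mode='binned'`` first quantizes each column to ``bins``
    equal-width levels and sums the integer levels, a discrete occurrence
    count. An all-zero column has no class preference: its entropy is defined
    as log2(t) (score 0, uninformative).
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    t = classes.size
    if t < 2:
        raise ValueError("at least 2 classes required")
    x = _minmax(values)
    if mode == "binned":
        x = np.floor(x * bins).clip(max=bins - 1)
    elif mode != "mass":
        raise ValueError(f"unknown mode {mode!r}; use 'mass' or 'binned'")
    D = x.shape[1]
    o = np.zeros((D, t))
    for j, c in enumerate(classes):
        o[:, j] = x[labels == c].sum(axis=0)
    totals = o.sum(axis=1)
    rf = np.zeros_like(o)
    nz = totals > 0
    rf[nz] = o[nz] / totals[nz, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rf > 0, rf * np.log2(rf), 0.0)
    entropy = -terms.sum(axis=1)
    entropy[~nz] = np.log2(t)  # all-zero column: uninformative by definition
    score = np.log2(t) - entropy
    return EntropyProfile(entropy=entropy, score=score, t=t, o=o, rf=rf, mode=mode)


def _rank(score: np.ndarray) -> np.ndarray:
    # stable sort on negated scores -> ties broken by lower column index
    return np.argsort(-score, kind="stable")


def select_by_mean_threshold(profile: EntropyProfile) -> SelectionResult:
    """Keep features scoring at or above the mean score (never empty)."""
    score = profile.score
    # small tolerance so exact ties with the mean are kept despite fp summation
    mask = score >= score.mean() - 1e-12 * (1 + abs(score.mean()))
    if not mask.any():  # unreachable for finite scores, kept as a guard
        mask[int(np.argmax(score))] = True
    return SelectionResult(mask, _rank(score), int(mask.sum()), "mean-threshold")


def select_top_k(profile: EntropyProfile, k: int) -> SelectionResult:
    """The k best-scoring features; ties broken by lower column index."""
    D = profile.score.size
    if not 1 <= k <= D:
        raise ValueError(f"k must be in 1..{D}, got {k}")
    ranked = _rank(profile.score)
    mask = np.zeros(D, dtype=bool)
    mask[ranked[:k]] = True
    return SelectionResult(mask, ranked, k, "top-k")


def iterative_entropy_selection(
    features: FeatureMatrix | np.ndarray,
    labels,
    evaluator: Callable[[np.ndarray], float],
    error_target: float = 0.1,
    max_rounds: int = 10,
    mode: str = "mass",
) -> SelectionResult:
    """Repeated mean-threshold selection until the classifier error drops.

    Each round re-scores the surviving feature pool, keeps the at-or-above-
    mean features, and asks ``evaluator(mask)`` (an error rate in [0,1]) about
    the candidate; the loop stops as soon as error < ``error_target`` (strict)
    or when rounds / shrinkage are exhausted. The best mask seen is returned;
    ``warning`` is set when the target was never met.
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    labels = np.asarray(labels, dtype=int)
    D = values.shape[1]
    pool = np.arange(D)
    best_mask, best_err = None, np.inf
    rounds = 0
    for _ in range(max_rounds):
        rounds += 1
        profile = feature_entropy(values[:, pool], labels, mode=mode)
        sel = select_by_mean_threshold(profile)
        keep = pool[sel.indices]
        mask = np.zeros(D, dtype=bool)
        mask[keep] = True
        err = float(evaluator(mask))
        if err < best_err:
            best_mask, best_err = mask, err
        if err < error_target:
            break
        if keep.size == pool.size:  # no shrinkage possible; nothing new to try
            break
        pool = keep
    warning = not best_err < error_target
    return SelectionResult(
        best_mask,
        _rank(feature_entropy(values, labels, mode=mode).score),
        int(best_mask.sum()),
        "iterative",
        error=best_err,
        warning=warning,
        rounds=rounds,
    )
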