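"""Classifier presets, cross-validation protocols, and per-class metrics.

Ten presets — five SVM kernels and five (plus cubic) k-NN variants — follow
the fine/medium/coarse conventions of desktop classification tools: Gaussian
kernel scales sqrt(D)/4, sqrt(D) and 4*sqrt(D), k of 1, 10 or 100. Metrics
are one-vs-rest per class:

    SEN = TP/(TP+FN), SPE = TN/(FP+TN), PRE = TP/(TP+FP),
    ACC = (TP+TN)/total, F1 = 2*PRE*SEN/(PRE+SEN)

reported as percentages, with the overall accuracy trace(CM)/total * 100.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

SVM_PRESETS = ("linear-svm", "quadratic-svm", "fine-gaussian-svm", "medium-gaussian-svm", "coarse-gaussian-svm")
KNN_PRESETS = ("fine-knn", "medium-knn", "coarse-knn", "cosine-knn", "weighted-knn", "cubic-knn")
ALL_PRESETS = SVM_PRESETS + KNN_PRESETS


@dataclass
class ClassifierSpec:
    family: str  # "svm" | "knn"
    preset: str
    params: dict = field(default_factory=dict)

    def build(self, n_features: int, n_train: int) -> Pipeline:
        """Resolve the preset into a fitted-ready sklearn pipeline."""
        p = dict(self.params)
        if self.family == "svm":
            clf = SVC(**p, decision_function_shape="ovo")
        else:
            p["n_neighbors"] = min(p["n_neighbors"], n_train)
            clf = KNeighborsClassifier(**p)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _inv_sq(d: np.ndarray) -> np.ndarray:
    return 1.0 / (d**2 + 1e-12)


def make_classifier(preset: str) -> ClassifierSpec:
    """Resolve a named preset into a fully specified classifier."""
    if preset == "linear-svm":
        return ClassifierSpec("svm", preset, {"kernel": "linear", "C": 1.0})
    if preset == "quadratic-svm":
        return ClassifierSpec("svm", preset, {"kernel": "poly", "degree": 2, "coef0": 1.0, "gamma": "scale", "C": 1.0})
    if preset.endswith("gaussian-svm"):
        # kernel scale sigma = sqrt(D)/4 | sqrt(D) | 4*sqrt(D); gamma = 1/sigma^2
        # depends on D, so only the factor is stored and resolved at fit time
        factor = {"fine-gaussian-svm": 0.25, "medium-gaussian-svm": 1.0, "coarse-gaussian-svm": 4.0}[preset]
        return ClassifierSpec("svm", preset, {"kernel": "rbf", "C": 1.0, "_scale_factor": factor})
    if preset == "fine-knn":
        return ClassifierSpec("knn", preset, {"n_neighbors": 1})
    if preset == "medium-knn":
        return ClassifierSpec("knn", preset, {"n_neighbors": 10})
    if preset == "coarse-knn":
        return ClassifierSpec("knn", preset, {"n_neighbors": 100})
    if preset == "cosine-knn":
        return ClassifierSpec("knn", preset, {"n_neighbors": 10, "metric": "cosine"})
    if preset == "weighted-knn":
        return ClassifierSpec("knn", preset, {"n_neighbors": 10, "weights": _inv_sq})
    if preset == "cubic-knn":
        return ClassifierSpec("knn", preset, {"n_neighbors": 10, "p": 3})
    raise ValueError(f"unknown preset {preset!r}; valid presets: {list(ALL_PRESETS)}")


def _resolve_params(spec: ClassifierSpec, n_features: int) -> ClassifierSpec:
    p = dict(spec.params)
    factor = p.pop("_scale_factor", None)
    if factor is not None:
        sigma = factor * np.sqrt(n_features)
        p["gamma"] = 1.0 / sigma**2
    return ClassifierSpec(spec.family, spec.preset, p)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (t, t), rows = true, cols = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def t(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, t: int) -> ConfusionMatrix:
    """t x t counts, entry (i, j) = samples of true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0 or max(y_true.max(), y_pred.max()) >= t):
        raise ValueError(f"labels must lie in 0..{t - 1}")
    counts = np.zeros((t, t), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def per_class_metrics(cm: ConfusionMatrix, c: int) -> tuple[float, float, float, float]:
    """(SEN, SPE, PRE, F1) in percent for class ``c``, one-vs-rest.

    Degenerate denominators (no true or no predicted positives) yield 0 for
    the affected metric, with a warning.
    """
    counts = cm.counts
    tp = int(counts[c, c])
    fn = int(counts[c].sum() - tp)
    fp = int(counts[:, c].sum() - tp)
    tn = int(counts.sum() - tp - fn - fp)
    if tp + fn == 0:
        warnings.warn(f"class {c} has no true samples; SEN set to 0")
        sen = 0.0
    else:
        sen = tp / (tp + fn)
    spe = tn / (fp + tn) if fp + tn else 0.0
    if tp + fp == 0:
        warnings.warn(f"class {c} has no predicted samples; PRE set to 0")
        pre = 0.0
    else:
        pre = tp / (tp + fp)
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return 100 * sen, 100 * spe, 100 * pre, 100 * f1


def class_accuracy(cm: ConfusionMatrix, c: int) -> float:
    """One-vs-rest accuracy (TP+TN)/total in percent for class ``c``."""
    counts = cm.counts
    tp = int(counts[c, c])
    fn = int(counts[c].sum() - tp)
    fp = int(counts[:, c].sum() - tp)
    tn = int(counts.sum() - tp - fn - fp)
    return 100 * (tp + tn) / max(cm.total, 1)


@dataclass
class EvaluationReport:
    preset: str
    cm: ConfusionMatrix
    per_class: dict[int, dict[str, float]]
    macro: dict[str, float]
    overall_acc: float
    wall_time: float
    protocol: str
    fold_assignment: np.ndarray | None = None

    def summary_row(self) -> dict[str, float | str]:
        return {
            "preset": self.preset,
            "ACC": self.overall_acc,
            "SEN": self.macro["SEN"],
            "PRE": self.macro["PRE"],
            "SPE": self.macro["SPE"],
            "F1": self.macro["F1"],
            "time_s": self.wall_time,
        }


def _report(preset: str, cm: ConfusionMatrix, wall: float, protocol: str, folds=None) -> EvaluationReport:
    per_class = {}
    for c in range(cm.t):
        sen, spe, pre, f1 = per_class_metrics(cm, c)
        per_class[c] = {"SEN": sen, "SPE": spe, "PRE": pre, "F1": f1, "ACC": class_accuracy(cm, c)}
    macro = {
        m: float(np.mean([per_class[c][m] for c in range(cm.t)])) for m in ("SEN", "SPE", "PRE", "F1")
    }
    overall = 100 * np.trace(cm.counts) / max(cm.total, 1)
    return EvaluationReport(preset, cm, per_class, macro, float(overall), wall, protocol, folds)


def _stratified_folds(labels: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold id per sample; each class spread as evenly as possible."""
    assign = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < n_folds:
            raise ValueError(f"class {c} has {idx.size} samples < {n_folds} folds")
        idx = idx[rng.permutation(idx.size)]
        assign[idx] = np.arange(idx.size) % n_folds
    return assign


def evaluate_protocol(
    features: FeatureMatrix | np.ndarray,
    labels,
    spec: ClassifierSpec,
    protocol: str | dict = "kfold:5",
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate one classifier preset under k-fold CV or a stratified holdout.

    ``protocol`` is ``"kfold:K"`` / ``{"kfold": K}`` (out-of-fold predictions
    pooled into a single confusion matrix) or ``"holdout:F"`` /
    ``{"holdout": F}`` with test fraction F (e.g. 0.30 for a 70:30 split).
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    t = int(y.max()) + 1
    if isinstance(protocol, str):
        kind, _, val = protocol.partition(":")
        protocol = {kind: float(val) if kind == "holdout" else int(val)}
    rng = np.random.default_rng(seed)
    spec = _resolve_params(spec, x.shape[1])
    t0 = time.perf_counter()
    if "kfold" in protocol:
        k = int(protocol["kfold"])
        folds = _stratified_folds(y, k, rng)
        y_pred = np.empty_like(y)
        for fold in range(k):
            te = folds == fold
            model = spec.build(x.shape[1], int((~te).sum()))
            model.fit(x[~te], y[~te])
            y_pred[te] = model.predict(x[te])
        cm = confusion_matrix(y, y_pred, t)
        return _report(spec.preset, cm, time.perf_counter() - t0, f"kfold:{k}", folds)
    if "holdout" in protocol:
        frac = float(protocol["holdout"])
        te_mask = np.zeros(y.size, dtype=bool)
        for c in classes:
            idx = np.flatnonzero(y == c)
            idx = idx[rng.permutation(idx.size)]
            te_mask[idx[: max(1, int(round(frac * idx.size)))]] = True
        model = spec.build(x.shape[1], int((~te_mask).sum()))
        model.fit(x[~te_mask], y[~te_mask])
        cm = confusion_matrix(y[te_mask], model.predict(x[te_mask]), t)
        return _report(spec.preset, cm, time.perf_counter() - t0, f"holdout:{frac}")
    raise ValueError(f"unknown protocol {protocol!r}")
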