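"""Deep CNN feature extractors: a 124-layer branching network and ResNet50.

The branching network ("GraphNet") is built to hard architectural
constraints — exactly 124 layer-graph nodes, at least one depth-concatenation
branch point, a global-average pool immediately before the first
fully-connected layer, and an FC-1 width of 4096 — with small, configurable
channel widths so it trains on a CPU. Layout arithmetic:

    input (1)
  + stem conv/BN/ReLU/maxpool (4)
  + 7 dual-branch blocks x 16 nodes each (112)
      block = 2 x (conv,BN,ReLU,conv,BN,ReLU) branches (12)
            + depth-concat (1) + 1x1 conv/BN/ReLU transition (3)
  + global-avg-pool, FC-1(4096), ReLU, dropout, FC-2(classes),
    softmax, classification-output (7)
  = 124

The ResNet50 extractor reproduces the standard bottleneck topology
(3/4/6/3 stages, widths 64..2048); its 2048-wide global-average-pool output is
the feature vector. Random initialization is permitted — the feature width is
architectural, not learned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .features import FeatureMatrix
from .preprocessing import Image, resize_image

NODE_KINDS = (
    "input",
    "conv",
    "batchnorm",
    "activation",
    "pool",
    "depth-concat",
    "addition",
    "dropout",
    "fully-connected",
    "softmax",
    "classification-output",
)

FC1_WIDTH = 4096
RESNET_WIDTH = 2048


@dataclass
class ArchitectureSpec:
    """Layer-graph summary: node (name, kind) list and edge list."""

    nodes: list[tuple[str, str]]
    edges: list[tuple[str, str]]
    fc1_width: int
    n_classes: int

    def validate(self) -> None:
        kinds = [k for _, k in self.nodes]
        for k in kinds:
            if k not in NODE_KINDS:
                raise ValueError(f"unknown node kind {k!r}")
        if kinds.count("input") != 1 or kinds.count("classification-output") != 1:
            raise ValueError("spec needs exactly one input and one classification-output")
        if "depth-concat" not in kinds:
            raise ValueError("branching layout requires at least one depth-concat node")
        if self.fc1_width != FC1_WIDTH:
            raise ValueError(f"fc1_width must be {FC1_WIDTH}")


def count_layers(spec: ArchitectureSpec) -> int:
    """Total layer count: every node of every kind counts as one layer."""
    return len(spec.nodes)


@dataclass
class TrainConfig:
    """SGDM training hyperparameters (minibatch 64, L2 1e-4, step LR drops)."""

    initial_lr: float = 0.001
    momentum: float = 0.9
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    max_epochs: int = 50
    minibatch: int = 64
    l2: float = 0.0001
    validation_frequency: int = 50
    shuffle_every_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_drop_factor < 1:
            raise ValueError("lr_drop_factor must be in (0,1)")
        if self.minibatch < 1 or self.max_epochs < 1:
            raise ValueError("minibatch and max_epochs must be >= 1")


class CNNModel:
    """A GraphModel plus its ArchitectureSpec and named feature taps."""

    def __init__(self, graph: nn.GraphModel, spec: ArchitectureSpec, taps: dict[str, str]):
        self.graph = graph
        self.spec = spec
        self.taps = taps  # public layer name -> graph node name

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.graph.forward(x, training=False)

    def features(self, x: np.ndarray, layer: str) -> np.ndarray:
        if layer not in self.taps:
            raise ValueError(f"unknown layer {layer!r}; valid layers: {sorted(self.taps)}")
        return self.graph.forward(x, training=False, upto=self.taps[layer])


def _branch(g: nn.GraphModel, prefix: str, src: str, cin: int, cout: int, rng) -> str:
    g.add(f"{prefix}_conv1", nn.Conv2d(cin, cout, 3, rng=rng), [src])
    g.add(f"{prefix}_bn1", nn.BatchNorm2d(cout))
    g.add(f"{prefix}_relu1", nn.ReLU())
    g.add(f"{prefix}_conv2", nn.Conv2d(cout, cout, 3, rng=rng))
    g.add(f"{prefix}_bn2", nn.BatchNorm2d(cout))
    g.add(f"{prefix}_relu2", nn.ReLU())
    return f"{prefix}_relu2"


def build_graphnet(
    n_classes: int,
    input_size: int,
    seed: int = 0,
    stem_channels: int = 8,
    block_channels: tuple[int, ...] = (8, 16, 16, 32, 32, 64, 64),
) -> CNNModel:
    """Build the 124-node branching CNN with seeded initialization.

    Works on any input size >= 32; spatial size is halved at the stem (twice)
    and at the transitions of blocks 2, 4 and 6.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if input_size < 32:
        raise ValueError("input_size must be >= 32")
    rng = np.random.default_rng(seed)
    g = nn.GraphModel(seed=seed)
    g.add("input", nn.Input(), [])
    g.add("stem_conv", nn.Conv2d(3, stem_channels, 3, stride=2, rng=rng))
    g.add("stem_bn", nn.BatchNorm2d(stem_channels))
    g.add("stem_relu", nn.ReLU())
    g.add("stem_pool", nn.MaxPool2d(2))
    cin = stem_channels
    prev = "stem_pool"
    for b, cb in enumerate(block_channels):
        a_out = _branch(g, f"b{b}a", prev, cin, cb, rng)
        b_out = _branch(g, f"b{b}b", prev, cin, cb, rng)
        g.add(f"b{b}_concat", nn.Concat(), [a_out, b_out])
        stride = 2 if b in (1, 3, 5) else 1
        g.add(f"b{b}_tconv", nn.Conv2d(2 * cb, cb, 1, stride=stride, pad=0, rng=rng))
        g.add(f"b{b}_tbn", nn.BatchNorm2d(cb))
        g.add(f"b{b}_trelu", nn.ReLU())
        prev = f"b{b}_trelu"
        cin = cb
    g.add("gap", nn.GlobalAvgPool())
    g.add("fc1", nn.Dense(cin, FC1_WIDTH, rng=rng))
    g.add("fc1_relu", nn.ReLU())
    g.add("drop", nn.Dropout(0.5, rng=np.random.default_rng(seed + 1)))
    g.add("fc2", nn.Dense(FC1_WIDTH, n_classes, rng=rng))
    g.add("softmax", nn.Softmax())
    g.add("out", nn.ClassificationOutput())

    nodes = [(n.name, n.kind) for n in g.nodes]
    edges = [(src, n.name) for n in g.nodes for src in n.inputs]
    spec = ArchitectureSpec(nodes, edges, FC1_WIDTH, n_classes)
    spec.validate()
    return CNNModel(g, spec, {"FC-1": "fc1", "GAP": "gap", "softmax": "softmax"})


def _bottleneck(g: nn.GraphModel, prefix: str, src: str, cin: int, cmid: int, stride: int, rng) -> str:
    cout = 4 * cmid
    g.add(f"{prefix}_c1", nn.Conv2d(cin, cmid, 1, stride=stride, pad=0, rng=rng), [src])
    g.add(f"{prefix}_b1", nn.BatchNorm2d(cmid))
    g.add(f"{prefix}_r1", nn.ReLU())
    g.add(f"{prefix}_c2", nn.Conv2d(cmid, cmid, 3, rng=rng))
    g.add(f"{prefix}_b2", nn.BatchNorm2d(cmid))
    g.add(f"{prefix}_r2", nn.ReLU())
    g.add(f"{prefix}_c3", nn.Conv2d(cmid, cout, 1, pad=0, rng=rng))
    g.add(f"{prefix}_b3", nn.BatchNorm2d(cout))
    if cin != cout or stride != 1:
        g.add(f"{prefix}_proj", nn.Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng), [src])
        g.add(f"{prefix}_projbn", nn.BatchNorm2d(cout))
        shortcut = f"{prefix}_projbn"
    else:
        shortcut = src
    g.add(f"{prefix}_add", nn.Add(), [f"{prefix}_b3", shortcut])
    g.add(f"{prefix}_out", nn.ReLU())
    return f"{prefix}_out"


def build_resnet50(seed: int = 0) -> CNNModel:
    """ResNet50-topology feature extractor (GAP output width 2048).

    Headless: ends at the global-average pool, which is the feature tap.
    """
    rng = np.random.default_rng(seed)
    g = nn.GraphModel(seed=seed)
    g.add("input", nn.Input(), [])
    g.add("stem_conv", nn.Conv2d(3, 64, 7, stride=2, pad=3, rng=rng))
    g.add("stem_bn", nn.BatchNorm2d(64))
    g.add("stem_relu", nn.ReLU())
    g.add("stem_pool", nn.MaxPool2d(3, stride=2, pad=1))
    prev, cin = "stem_pool", 64
    for s, (cmid, reps) in enumerate(zip((64, 128, 256, 512), (3, 4, 6, 3))):
        for r in range(reps):
            stride = 2 if (s > 0 and r == 0) else 1
            prev = _bottleneck(g, f"s{s}_{r}", prev, cin, cmid, stride, rng)
            cin = 4 * cmid
    g.add("gap", nn.GlobalAvgPool())
    nodes = [(n.name, n.kind) for n in g.nodes]
    edges = [(src, n.name) for n in g.nodes for src in n.inputs]
    spec = ArchitectureSpec(nodes, edges, FC1_WIDTH, 0)  # headless: not validated
    return CNNModel(g, spec, {"GAP": "gap"})


def _to_batch(images, size: int | None = None) -> np.ndarray:
    """Stack images to NCHW float32 in [0,1], optionally resizing."""
    arrs = []
    for img in images:
        px = img.pixels if isinstance(img, Image) else np.asarray(img)
        if size is not None and px.shape[:2] != (size, size):
            px = resize_image(px, size)
        px = np.asarray(px, dtype=np.float32)
        if px.ndim == 2:
            px = np.repeat(px[..., None], 3, axis=2)
        arrs.append(px.transpose(2, 0, 1) / 255.0)
    return np.stack(arrs)


def train_cnn(model: CNNModel, images, labels, cfg: TrainConfig, val=None) -> dict:
    """Train with SGD + momentum; returns a per-epoch history.

    History keys: ``loss``, ``accuracy``, ``lr`` (length ``max_epochs``) and,
    when a validation set is supplied, ``val`` with (iteration, accuracy)
    pairs recorded every ``validation_frequency`` minibatch iterations.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    x = _to_batch(images)
    opt = nn.SGDMomentum(model.graph, cfg.initial_lr, cfg.momentum, cfg.l2)
    rng = np.random.default_rng(cfg.seed)
    history: dict = {"loss": [], "accuracy": [], "lr": [], "val": []}
    iteration = 0
    n = x.shape[0]
    for epoch in range(cfg.max_epochs):
        lr = cfg.initial_lr * cfg.lr_drop_factor ** (epoch // cfg.lr_drop_period)
        opt.lr = lr
        order = rng.permutation(n) if cfg.shuffle_every_epoch else np.arange(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.minibatch):
            idx = order[start : start + cfg.minibatch]
            logits = model.graph.forward_logits(x[idx], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/Inf loss at epoch {epoch}, iteration {iteration}; "
                    "reduce the learning rate or check the input scaling"
                )
            model.graph.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
            iteration += 1
            if val is not None and iteration % cfg.validation_frequency == 0:
                vx, vy = val
                vlogits = model.graph.forward_logits(_to_batch(vx), training=False)
                history["val"].append((iteration, float((vlogits.argmax(1) == vy).mean())))
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
        history["lr"].append(lr)
    return history


def extract_deep_features(model: CNNModel, images, layer: str = "FC-1", batch: int = 16) -> FeatureMatrix:
    """Row-aligned feature matrix from a named layer (``FC-1`` -> N x 4096)."""
    x = _to_batch(images)
    rows = [model.features(x[i : i + batch], layer) for i in range(0, x.shape[0], batch)]
    values = np.vstack(rows).astype(float)
    return FeatureMatrix(values, ["graphnet"] * values.shape[1])


def extract_backbone_features(
    images, backbone: str = "resnet50", input_size: int = 224, seed: int = 0,
    model: CNNModel | None = None, batch: int = 8,
) -> FeatureMatrix:
    """N x 2048 global-average-pool features from the ResNet50 topology.

    A prebuilt ``model`` (e.g. with loaded weights) may be passed; otherwise a
    seeded randomly-initialized backbone is constructed.
    """
    if backbone != "resnet50":
        raise ValueError(f"unknown backbone {backbone!r}; available: resnet50")
    if model is None:
        model = build_resnet50(seed=seed)
    x = _to_batch(images, size=input_size)
    rows = [model.features(x[i : i + batch], "GAP") for i in range(0, x.shape[0], batch)]
    values = np.vstack(rows).astype(float)
    return FeatureMatrix(values, ["resnet"] * values.shape[1])
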