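"""Minimal seeded layer-graph neural-network engine (numpy, NCHW).

Supports the node kinds needed by the branching CNN and the ResNet50-topology
backbone: conv, batchnorm, activation (ReLU), max/global-average pooling,
depth-concat, addition, dropout, fully-connected, softmax and a
classification-output node. Convolution uses im2col + BLAS matmul; training
uses SGD with momentum, L2 weight decay and step learning-rate drops.

Only what the package needs is implemented; this is a compact engine, not a
general framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32


# --------------------------------------------------------------------- layers
class Layer:
    """Base: forward caches what backward needs; params/grads are dicts."""

    kind = "layer"

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, xs: list[np.ndarray], training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> list[np.ndarray]:  # pragma: no cover
        raise NotImplementedError


class Input(Layer):
    kind = "input"

    def forward(self, xs, training):
        return xs[0]

    def backward(self, gout):
        return [gout]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N*OH*OW, C*k*k) patch matrix."""
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    OH = (Hp - k) // stride + 1
    OW = (Wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,OH,OW,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * OH * OW, C * k * k)
    return np.ascontiguousarray(cols), (N, C, Hp, Wp, OH, OW)


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, pad: int) -> np.ndarray:
    N, C, Hp, Wp, OH, OW = shape
    dxp = np.zeros((N, C, Hp, Wp), dtype=dcols.dtype)
    d = dcols.reshape(N, OH, OW, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += d[..., i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    kind = "conv"

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int | None = None, rng=None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = (rng.normal(0, np.sqrt(2.0 / fan_in), (cout, fan_in))).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, xs, training):
        x = xs[0]
        cols, self._shape = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols if training else None
        N, _, _, _, OH, OW = self._shape
        out = cols @ self.W.T + self.b
        return out.reshape(N, OH, OW, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gout):
        N, C, Hp, Wp, OH, OW = self._shape
        g = gout.transpose(0, 2, 3, 1).reshape(N * OH * OW, self.cout)
        self.dW[...] = g.T @ self._cols
        self.db[...] = g.sum(axis=0)
        dcols = g @ self.W
        return [_col2im(dcols, self._shape, self.k, self.stride, self.pad)]


class BatchNorm2d(Layer):
    kind = "batchnorm"

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, xs, training):
        x = xs[0]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._xhat, self._inv = xhat, inv
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, gout):
        xhat, inv = self._xhat, self._inv
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        self.dgamma[...] = (gout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = gout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = gout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return [dx.astype(DTYPE)]


class ReLU(Layer):
    kind = "activation"

    def forward(self, xs, training):
        x = xs[0]
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return [gout * self._mask]


class MaxPool2d(Layer):
    kind = "pool"

    def __init__(self, k: int = 2, stride: int | None = None, pad: int = 0):
        self.k, self.stride, self.pad = k, stride or k, pad

    def forward(self, xs, training):
        x = xs[0]
        N, C = x.shape[:2]
        cols, self._shape = _im2col(x, self.k, self.stride, self.pad)
        _, _, _, _, OH, OW = self._shape
        cols = cols.reshape(N * OH * OW, C, self.k * self.k)
        self._arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, self._arg[..., None], axis=2)[..., 0]
        return out.reshape(N, OH, OW, C).transpose(0, 3, 1, 2)

    def backward(self, gout):
        N, C, Hp, Wp, OH, OW = self._shape
        g = gout.transpose(0, 2, 3, 1).reshape(N * OH * OW, C)
        dcols = np.zeros((N * OH * OW, C, self.k * self.k), dtype=gout.dtype)
        np.put_along_axis(dcols, self._arg[..., None], g[..., None], axis=2)
        return [_col2im(dcols.reshape(N * OH * OW, C * self.k * self.k), self._shape, self.k, self.stride, self.pad)]


class GlobalAvgPool(Layer):
    kind = "pool"

    def forward(self, xs, training):
        x = xs[0]
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        H, W = self._hw
        return [np.repeat(gout[:, :, None, None], H, axis=2).repeat(W, axis=3) / (H * W)]


class Concat(Layer):
    kind = "depth-concat"

    def forward(self, xs, training):
        self._splits = np.cumsum([x.shape[1] for x in xs])[:-1]
        return np.concatenate(xs, axis=1)

    def backward(self, gout):
        return np.split(gout, self._splits, axis=1)


class Add(Layer):
    kind = "addition"

    def __init__(self):
        self._n = 2

    def forward(self, xs, training):
        self._n = len(xs)
        out = xs[0].copy()
        for x in xs[1:]:
            out += x
        return out

    def backward(self, gout):
        return [gout] * self._n


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, p: float = 0.5, rng=None):
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, xs, training):
        x = xs[0]
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask.astype(DTYPE)

    def backward(self, gout):
        if self._mask is None:
            return [gout]
        return [gout * self._mask.astype(DTYPE)]


class Dense(Layer):
    kind = "fully-connected"

    def __init__(self, din: int, dout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0, np.sqrt(2.0 / din), (din, dout)).astype(DTYPE)
        self.b = np.zeros(dout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, xs, training):
        self._x = xs[0]
        return self._x @ self.W + self.b

    def backward(self, gout):
        self.dW[...] = self._x.T @ gout
        self.db[...] = gout.sum(axis=0)
        return [gout @ self.W.T]


class Softmax(Layer):
    kind = "softmax"

    def forward(self, xs, training):
        z = xs[0] - xs[0].max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, gout):  # training bypasses softmax (fused CE grad)
        return [gout]


class ClassificationOutput(Layer):
    kind = "classification-output"

    def forward(self, xs, training):
        return xs[0]

    def backward(self, gout):
        return [gout]


# ---------------------------------------------------------------- layer graph
@dataclass
class Node:
    name: str
    layer: Layer
    inputs: list[str] = field(default_factory=list)

    @property
    def kind(self) -> str:
        return self.layer.kind


class GraphModel:
    """DAG of layers, built in topological order (inputs precede use)."""

    def __init__(self, seed: int = 0):
        self.nodes: list[Node] = []
        self._by_name: dict[str, Node] = {}
        self.seed = seed
        self.rng = np.random.default_rng(seed)

    def add(self, name: str, layer: Layer, inputs: list[str] | None = None) -> str:
        if name in self._by_name:
            raise ValueError(f"duplicate node {name!r}")
        inputs = inputs if inputs is not None else ([self.nodes[-1].name] if self.nodes else [])
        for i in inputs:
            if i not in self._by_name:
                raise ValueError(f"node {name!r} references unknown input {i!r}")
        node = Node(name, layer, list(inputs))
        self.nodes.append(node)
        self._by_name[name] = node
        return name

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def _run(self, x: np.ndarray, training: bool, upto: str | None = None) -> dict[str, np.ndarray]:
        values: dict[str, np.ndarray] = {}
        for node in self.nodes:
            if node.kind == "input":
                values[node.name] = x.astype(DTYPE)
            else:
                values[node.name] = node.layer.forward([values[i] for i in node.inputs], training)
            if upto is not None and node.name == upto:
                break
        return values

    def forward(self, x: np.ndarray, training: bool = False, upto: str | None = None) -> np.ndarray:
        """Output of node ``upto`` (default: the final node)."""
        values = self._run(x, training, upto)
        return values[upto if upto is not None else self.nodes[-1].name]

    def logits_node(self) -> str:
        """Node feeding the softmax (training loss is computed on its output)."""
        for node in self.nodes:
            if node.kind == "softmax":
                return node.inputs[0]
        return self.nodes[-1].name

    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.forward(x, training=training, upto=self.logits_node())

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop from the logits node through the DAG."""
        target = self.logits_node()
        grads: dict[str, np.ndarray] = {target: dlogits.astype(DTYPE)}
        # walk nodes in reverse build order up to the logits node
        idx = self.node_names.index(target)
        for node in reversed(self.nodes[: idx + 1]):
            if node.name not in grads or node.kind == "input":
                continue
            gins = node.layer.backward(grads.pop(node.name))
            for src, g in zip(node.inputs, gins):
                if src in grads:
                    grads[src] = grads[src] + g
                else:
                    grads[src] = g

    def parameters(self):
        """Yield (node_name, param_name, value, grad) for all trainable params."""
        for node in self.nodes:
            p, g = node.layer.params(), node.layer.grads()
            for k in p:
                yield node.name, k, p[k], g[k]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for node in self.nodes:
            for k, v in node.layer.params().items():
                state[f"{node.name}.{k}"] = v
            if isinstance(node.layer, BatchNorm2d):
                state[f"{node.name}.running_mean"] = node.layer.running_mean
                state[f"{node.name}.running_var"] = node.layer.running_var
        return state

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def load(self, path) -> None:
        data = np.load(path)
        for node in self.nodes:
            for k, v in node.layer.params().items():
                v[...] = data[f"{node.name}.{k}"]
            if isinstance(node.layer, BatchNorm2d):
                node.layer.running_mean = data[f"{node.name}.running_mean"]
                node.layer.running_var = data[f"{node.name}.running_var"]


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss and gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class SGDMomentum:
    """SGD with classical momentum, L2 penalty, and step LR drops."""

    def __init__(self, model: GraphModel, lr: float, momentum: float = 0.9, l2: float = 1e-4):
        self.model = model
        self.lr, self.momentum, self.l2 = lr, momentum, l2
        self.velocity: dict[tuple[str, str], np.ndarray] = {}

    def step(self) -> None:
        for node, name, p, g in self.model.parameters():
            key = (node, name)
            # L2 only on weight matrices, not biases/BN offsets
            decay = self.l2 if name == "W" else 0.0
            v = self.velocity.get(key)
            if v is None:
                v = np.zeros_like(p)
            v = self.momentum * v - self.lr * (g + decay * p)
            self.velocity[key] = v
            p += v
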