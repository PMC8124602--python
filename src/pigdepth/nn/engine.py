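"""Static computation graph with NHWC inference-mode layers.

Parameter conventions match the common framework defaults: convolutions
store (kh, kw, cin_per_group, cout) weights; batch normalization stores
gamma/beta (trainable) plus moving mean/variance (non-trainable); dense
layers store (fin, fout) plus bias. "Same" padding follows the asymmetric
convention pad_total = max((ceil(n/s)-1)*s + k - n, 0), padded more on the
bottom/right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "DepthwiseConv2D",
    "BatchNorm",
    "Activation",
    "ZeroPad",
    "MaxPool",
    "AvgPool",
    "GlobalAvgPool",
    "Dense",
    "Add",
    "Concat",
    "Graph",
]


@dataclass
class Param:
    name: str
    value: np.ndarray
    trainable: bool = True

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: holds parameters, computes output shape and forward."""

    def __init__(self, name: str):
        self.name = name
        self.params: list[Param] = []

    def _add_param(self, suffix: str, value: np.ndarray, trainable: bool = True) -> Param:
        p = Param(f"{self.name}/{suffix}", np.asarray(value, dtype=np.float32), trainable)
        self.params.append(p)
        return p

    def out_shape(self, shapes: list[tuple]) -> tuple:
        raise NotImplementedError

    def forward(self, xs: list[np.ndarray]) -> np.ndarray:
        raise NotImplementedError


def _same_pads(n: int, k: int, s: int) -> tuple[int, int]:
    total = max((math.ceil(n / s) - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def _pad2d(x: np.ndarray, ph: tuple[int, int], pw: tuple[int, int], value: float = 0.0) -> np.ndarray:
    if ph == (0, 0) and pw == (0, 0):
        return x
    return np.pad(x, ((0, 0), ph, pw, (0, 0)), constant_values=value)


def _pool_size(n: int, k: int, s: int, padding: str) -> int:
    if padding == "same":
        return math.ceil(n / s)
    return (n - k) // s + 1


def _windows(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,H,W,C) -> (N,Ho,Wo,C,kh,kw) view of sliding windows."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    return v[:, ::sh, ::sw]


class Conv2D(Layer):
    def __init__(self, name, cin, cout, kernel, stride=1, padding="same", use_bias=True):
        super().__init__(name)
        self.cin, self.cout, self.k, self.s = cin, cout, kernel, stride
        self.padding = padding
        self.use_bias = use_bias
        fan_in = kernel * kernel * cin
        scale = math.sqrt(2.0 / fan_in)
        rng = np.random.default_rng(abs(hash(name)) % (2**32))
        self.w = self._add_param(
            "kernel", rng.normal(0.0, scale, (kernel, kernel, cin, cout))
        )
        self.b = self._add_param("bias", np.zeros(cout)) if use_bias else None

    def out_shape(self, shapes):
        n, h, w, c = shapes[0]
        assert c == self.cin, f"{self.name}: expected {self.cin} channels, got {c}"
        if self.padding == "same":
            ho, wo = math.ceil(h / self.s), math.ceil(w / self.s)
        else:
            ho, wo = (h - self.k) // self.s + 1, (w - self.k) // self.s + 1
        return (n, ho, wo, self.cout)

    def forward(self, xs):
        x = xs[0]
        if self.padding == "same":
            ph = _same_pads(x.shape[1], self.k, self.s)
            pw = _same_pads(x.shape[2], self.k, self.s)
            x = _pad2d(x, ph, pw)
        win = _windows(x, self.k, self.k, self.s, self.s)  # N,Ho,Wo,C,kh,kw
        n, ho, wo = win.shape[:3]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, -1)
        wmat = self.w.value.transpose(0, 1, 2, 3).reshape(-1, self.cout)
        out = cols @ wmat
        if self.b is not None:
            out += self.b.value
        return out.reshape(n, ho, wo, self.cout)


class DepthwiseConv2D(Layer):
    def __init__(self, name, cin, kernel, stride=1, padding="same", use_bias=False):
        super().__init__(name)
        self.cin, self.k, self.s = cin, kernel, stride
        self.padding = padding
        rng = np.random.default_rng(abs(hash(name)) % (2**32))
        scale = math.sqrt(2.0 / (kernel * kernel))
        self.w = self._add_param(
            "depthwise_kernel", rng.normal(0.0, scale, (kernel, kernel, cin))
        )
        self.b = self._add_param("bias", np.zeros(cin)) if use_bias else None

    def out_shape(self, shapes):
        n, h, w, c = shapes[0]
        assert c == self.cin
        if self.padding == "same":
            ho, wo = math.ceil(h / self.s), math.ceil(w / self.s)
        else:
            ho, wo = (h - self.k) // self.s + 1, (w - self.k) // self.s + 1
        return (n, ho, wo, self.cin)

    def forward(self, xs):
        x = xs[0]
        if self.padding == "same":
            ph = _same_pads(x.shape[1], self.k, self.s)
            pw = _same_pads(x.shape[2], self.k, self.s)
            x = _pad2d(x, ph, pw)
        win = _windows(x, self.k, self.k, self.s, self.s)  # N,Ho,Wo,C,kh,kw
        out = np.einsum("nhwckl,klc->nhwc", win, self.w.value, optimize=True)
        if self.b is not None:
            out += self.b.value
        return out


class BatchNorm(Layer):
    """Inference-mode batch normalization over the channel axis."""

    def __init__(self, name, c, eps=1e-3):
        super().__init__(name)
        self.c, self.eps = c, eps
        self.gamma = self._add_param("gamma", np.ones(c))
        self.beta = self._add_param("beta", np.zeros(c))
        self.mean = self._add_param("moving_mean", np.zeros(c), trainable=False)
        self.var = self._add_param("moving_variance", np.ones(c), trainable=False)

    def out_shape(self, shapes):
        return shapes[0]

    def forward(self, xs):
        x = xs[0]
        inv = self.gamma.value / np.sqrt(self.var.value + self.eps)
        return x * inv + (self.beta.value - self.mean.value * inv)


class Activation(Layer):
    def __init__(self, name, kind="relu"):
        super().__init__(name)
        if kind not in ("relu", "relu6"):
            raise ValueError(f"unsupported activation {kind!r}")
        self.kind = kind

    def out_shape(self, shapes):
        return shapes[0]

    def forward(self, xs):
        x = np.maximum(xs[0], 0.0)
        if self.kind == "relu6":
            x = np.minimum(x, 6.0)
        return x


class ZeroPad(Layer):
    def __init__(self, name, pads):
        super().__init__(name)
        # pads: ((top, bottom), (left, right))
        self.pads = pads

    def out_shape(self, shapes):
        n, h, w, c = shapes[0]
        (t, b), (l, r) = self.pads
        return (n, h + t + b, w + l + r, c)

    def forward(self, xs):
        (t, b), (l, r) = self.pads
        return _pad2d(xs[0], (t, b), (l, r))


class MaxPool(Layer):
    def __init__(self, name, pool, stride, padding="valid"):
        super().__init__(name)
        self.k, self.s, self.padding = pool, stride, padding

    def out_shape(self, shapes):
        n, h, w, c = shapes[0]
        return (n, _pool_size(h, self.k, self.s, self.padding),
                _pool_size(w, self.k, self.s, self.padding), c)

    def forward(self, xs):
        x = xs[0]
        if self.padding == "same":
            ph = _same_pads(x.shape[1], self.k, self.s)
            pw = _same_pads(x.shape[2], self.k, self.s)
            x = _pad2d(x, ph, pw, value=-np.inf)
        win = _windows(x, self.k, self.k, self.s, self.s)
        return win.max(axis=(4, 5))


class AvgPool(Layer):
    def __init__(self, name, pool, stride, padding="valid"):
        super().__init__(name)
        self.k, self.s, self.padding = pool, stride, padding

    def out_shape(self, shapes):
        n, h, w, c = shapes[0]
        return (n, _pool_size(h, self.k, self.s, self.padding),
                _pool_size(w, self.k, self.s, self.padding), c)

    def forward(self, xs):
        x = xs[0]
        if self.padding == "same":
            # average over valid (unpadded) entries only
            ph = _same_pads(x.shape[1], self.k, self.s)
            pw = _same_pads(x.shape[2], self.k, self.s)
            ones = np.ones_like(x[..., :1])
            x = _pad2d(x, ph, pw)
            ones = _pad2d(ones, ph, pw)
            win = _windows(x, self.k, self.k, self.s, self.s)
            cnt = _windows(ones, self.k, self.k, self.s, self.s).sum(axis=(4, 5))
            return win.sum(axis=(4, 5)) / cnt
        win = _windows(x, self.k, self.k, self.s, self.s)
        return win.mean(axis=(4, 5))


class GlobalAvgPool(Layer):
    def out_shape(self, shapes):
        n, h, w, c = shapes[0]
        return (n, c)

    def forward(self, xs):
        return xs[0].mean(axis=(1, 2))


class Dense(Layer):
    def __init__(self, name, fin, fout, use_bias=True, w_init="glorot"):
        super().__init__(name)
        self.fin, self.fout = fin, fout
        if w_init == "zeros":
            w = np.zeros((fin, fout))
        else:
            limit = math.sqrt(6.0 / (fin + fout))
            rng = np.random.default_rng(abs(hash(name)) % (2**32))
            w = rng.uniform(-limit, limit, (fin, fout))
        self.w = self._add_param("kernel", w)
        self.b = self._add_param("bias", np.zeros(fout)) if use_bias else None

    def out_shape(self, shapes):
        n = shapes[0][0]
        return (n, self.fout)

    def forward(self, xs):
        out = xs[0] @ self.w.value
        if self.b is not None:
            out += self.b.value
        return out


class Add(Layer):
    def out_shape(self, shapes):
        return shapes[0]

    def forward(self, xs):
        out = xs[0].copy()
        for x in xs[1:]:
            out += x
        return out


class Concat(Layer):
    def out_shape(self, shapes):
        c = sum(s[-1] for s in shapes)
        return shapes[0][:-1] + (c,)

    def forward(self, xs):
        return np.concatenate(xs, axis=-1)


@dataclass
class _Node:
    layer: Layer
    inputs: tuple[str, ...]
    output: str


class Graph:
    """A static DAG of layers; tensors are referenced by name."""

    def __init__(self, input_shape: tuple):
        """input_shape: (H, W, C) of a single sample."""
        self.input_shape = input_shape
        self.nodes: list[_Node] = []
        self._shapes: dict[str, tuple] = {"input": (None,) + tuple(input_shape)}
        self._names: set[str] = set()

    def add(self, layer: Layer, *inputs: str) -> str:
        if layer.name in self._names:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        self._names.add(layer.name)
        for t in inputs:
            if t not in self._shapes:
                raise KeyError(f"unknown tensor {t!r}")
        out = layer.name
        self._shapes[out] = layer.out_shape([self._shapes[t] for t in inputs])
        self.nodes.append(_Node(layer, tuple(inputs), out))
        return out

    def shape(self, tensor: str) -> tuple:
        return self._shapes[tensor]

    @property
    def output(self) -> str:
        return self.nodes[-1].output

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} != expected {self.input_shape}"
            )
        # reference counting so intermediate maps are freed eagerly
        counts: dict[str, int] = {}
        for node in self.nodes:
            for t in node.inputs:
                counts[t] = counts.get(t, 0) + 1
        cache: dict[str, np.ndarray] = {"input": x}
        out = x
        for node in self.nodes:
            out = node.layer.forward([cache[t] for t in node.inputs])
            cache[node.output] = out
            for t in node.inputs:
                counts[t] -= 1
                if counts[t] == 0 and t != "input":
                    del cache[t]
        return out

    def parameters(self) -> list[Param]:
        return [p for node in self.nodes for p in node.layer.params]

    def count_parameters(self) -> tuple[int, int]:
        """(total, trainable) parameter counts."""
        total = sum(p.size for p in self.parameters())
        trainable = sum(p.size for p in self.parameters() if p.trainable)
        return total, trainable
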