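"""Trainable small CNN: four conv-BN-ReLU-maxpool blocks, global average
pooling, six parallel single-node linear heads.

Forward and backward passes are written directly on NumPy (im2col
convolutions); this is the only backbone with gradient support in this
engine, sized so the full training loop runs in minutes on one CPU core.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["TinyNet"]


class _TParam:
    __slots__ = ("name", "value", "trainable", "grad")

    def __init__(self, name, value, trainable=True):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.trainable = trainable
        self.grad = np.zeros_like(self.value)

    @property
    def size(self):
        return int(self.value.size)


class _ConvBlock:
    """Conv 3x3 same (no bias) -> batch norm -> ReLU -> 2x2 max pool."""

    def __init__(self, name, cin, cout, rng):
        scale = math.sqrt(2.0 / (9 * cin))
        self.w = _TParam(f"{name}/kernel", rng.normal(0, scale, (3, 3, cin, cout)))
        self.gamma = _TParam(f"{name}/gamma", np.ones(cout))
        self.beta = _TParam(f"{name}/beta", np.zeros(cout))
        self.rmean = _TParam(f"{name}/moving_mean", np.zeros(cout), trainable=False)
        self.rvar = _TParam(f"{name}/moving_variance", np.ones(cout), trainable=False)
        self.cin, self.cout = cin, cout
        self.momentum = 0.9
        self.eps = 1e-3

    @property
    def params(self):
        return [self.w, self.gamma, self.beta, self.rmean, self.rvar]

    def forward(self, x, training):
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)
        wmat = self.w.value.reshape(-1, self.cout)
        z = (cols @ wmat).reshape(n, h, w, self.cout)
        # batch norm
        if training:
            mean = z.mean(axis=(0, 1, 2))
            var = z.var(axis=(0, 1, 2))
            self.rmean.value = self.momentum * self.rmean.value + (1 - self.momentum) * mean
            self.rvar.value = self.momentum * self.rvar.value + (1 - self.momentum) * var
        else:
            mean, var = self.rmean.value, self.rvar.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (z - mean) * inv
        a = np.maximum(self.gamma.value * xhat + self.beta.value, 0.0)
        # 2x2 max pool, stride 2 (even spatial sizes assumed)
        ar = a.reshape(n, h // 2, 2, w // 2, 2, self.cout)
        flat = ar.transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, self.cout)
        idx = flat.argmax(axis=3)
        out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if training:
            self._cache = (cols, (n, h, w), xhat, inv, a > 0, idx, flat.shape)
        return out

    def backward(self, dout):
        cols, (n, h, w), xhat, inv, relu_mask, idx, flat_shape = self._cache
        # max pool backward (gradient to the argmax element only)
        dflat = np.zeros(flat_shape)
        np.put_along_axis(dflat, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        da = (
            dflat.reshape(n, h // 2, w // 2, 2, 2, self.cout)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, self.cout)
        )
        # ReLU
        da = da * relu_mask
        # batch norm backward
        m = n * h * w
        self.gamma.grad += (da * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += da.sum(axis=(0, 1, 2))
        dz = (self.gamma.value * inv / m) * (
            m * da
            - da.sum(axis=(0, 1, 2))
            - xhat * (da * xhat).sum(axis=(0, 1, 2))
        )
        # conv backward
        dz_flat = dz.reshape(n * h * w, self.cout)
        self.w.grad += (cols.T @ dz_flat).reshape(self.w.value.shape)
        dcols = dz_flat @ self.w.value.reshape(-1, self.cout).T
        dwin = dcols.reshape(n, h, w, 3, 3, self.cin)
        dxp = np.zeros((n, h + 2, w + 2, self.cin))
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w, :] += dwin[:, :, :, i, j, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class _Head:
    """Single-node linear dense layer on the pooled features."""

    def __init__(self, name, fin, rng, w_init="glorot", bias_init=0.0):
        if w_init == "zeros":
            w = np.zeros((fin, 1))
        else:
            limit = math.sqrt(6.0 / (fin + 1))
            w = rng.uniform(-limit, limit, (fin, 1))
        self.w = _TParam(f"{name}/kernel", w)
        self.b = _TParam(f"{name}/bias", np.full(1, float(bias_init)))

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, feats):
        return feats @ self.w.value + self.b.value

    def backward(self, dy, feats):
        self.w.grad += feats.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class TinyNet:
    """Trainable multiple-output regressor (see module docstring)."""

    CHANNELS = (16, 32, 64, 128)

    def __init__(
        self,
        input_size: int = 64,
        seed: int = 0,
        head_w_init: str = "glorot",
        head_bias_init=None,
        head_names=("BW", "SW", "SH", "HW", "HH", "BL"),
        input_offset: float = 127.5,
        input_scale: float = 127.5,
    ):
        if input_size % 16 != 0:
            raise ValueError(
                f"tinycnn input_size must be a multiple of 16, got {input_size}"
            )
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.input_offset = input_offset
        self.input_scale = input_scale
        self.blocks = []
        cin = 3
        for i, c in enumerate(self.CHANNELS, start=1):
            self.blocks.append(_ConvBlock(f"conv{i}", cin, c, rng))
            cin = c
        self.feature_width = cin
        if head_bias_init is None:
            head_bias_init = np.zeros(len(head_names))
        head_bias_init = np.asarray(head_bias_init, dtype=float).ravel()
        self.heads = [
            _Head(f"head_{nm}", cin, rng, head_w_init, head_bias_init[i])
            for i, nm in enumerate(head_names)
        ]

    # --- parameter bookkeeping -------------------------------------------
    def parameters(self):
        out = []
        for blk in self.blocks:
            out.extend(blk.params)
        for head in self.heads:
            out.extend(head.params)
        return out

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.trainable]

    def zero_grads(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def get_weights(self):
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights):
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value = np.asarray(w, dtype=np.float64).copy()

    # --- forward / backward ----------------------------------------------
    def _to_input(self, images):
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 4 and x.shape[-1] == 1:
            x = x[..., 0]
        if x.ndim != 3 or x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected gray images of shape (n, {self.input_size}, "
                f"{self.input_size}), got {np.shape(images)}"
            )
        x = (x - self.input_offset) / self.input_scale
        return np.repeat(x[..., None], 3, axis=-1)

    def forward(self, images, training=False):
        x = self._to_input(images)
        for blk in self.blocks:
            x = blk.forward(x, training)
        feats = x.mean(axis=(1, 2))
        if training:
            self._feats = feats
            self._spatial = x.shape[1:3]
        return np.concatenate([h.forward(feats) for h in self.heads], axis=1)

    def backward(self, dy):
        """Accumulate gradients for a (n, 6) upstream gradient."""
        dfeats = np.zeros_like(self._feats)
        for j, head in enumerate(self.heads):
            dfeats += head.backward(dy[:, j : j + 1], self._feats)
        hh, ww = self._spatial
        dx = np.repeat(
            np.repeat(dfeats[:, None, None, :] / (hh * ww), hh, axis=1), ww, axis=2
        )
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)

    def predict(self, images, batch_size: int = 64):
        images = np.asarray(images)
        if images.ndim == 2:
            images = images[None]
        outs = [
            self.forward(images[i : i + batch_size], training=False)
            for i in range(0, len(images), batch_size)
        ]
        return np.concatenate(outs, axis=0)
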