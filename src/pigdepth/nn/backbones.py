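"""Convolutional backbone graphs, each ending in global average pooling.

The four reference extractors (densenet201, resnet152v2, xception,
mobilenetv2) follow their published definitions layer by layer, so their
parameter tallies match the widely used framework implementations exactly.
`tinycnn` is a small four-block backbone for desk-scale training and is not
one of the reference architectures.
"""

from __future__ import annotations

from pigdepth.nn.engine import (
    Activation,
    Add,
    AvgPool,
    BatchNorm,
    Concat,
    Conv2D,
    DepthwiseConv2D,
    GlobalAvgPool,
    Graph,
    MaxPool,
    ZeroPad,
)

__all__ = ["BACKBONES", "build_backbone", "feature_width"]

#: backbone name -> (default input size, pooled feature width)
BACKBONES: dict[str, tuple[int, int]] = {
    "densenet201": (224, 1920),
    "mobilenetv2": (224, 1280),
    "resnet152v2": (224, 2048),
    "xception": (299, 2048),
    "tinycnn": (64, 128),
}


class _B:
    """Tiny builder wrapper: tracks the running tensor and channel count."""

    def __init__(self, g: Graph):
        self.g = g
        self.t = "input"
        self.c = g.input_shape[-1]

    def conv(self, name, cout, k, s=1, pad="same", bias=True):
        self.t = self.g.add(Conv2D(name, self.c, cout, k, s, pad, bias), self.t)
        self.c = cout
        return self.t

    def dwconv(self, name, k, s=1, pad="same"):
        self.t = self.g.add(DepthwiseConv2D(name, self.c, k, s, pad), self.t)
        return self.t

    def sepconv(self, name, cout, k, s=1, pad="same"):
        """Depthwise followed by pointwise, both bias-free."""
        self.dwconv(name + "_dw", k, s, pad)
        self.t = self.g.add(Conv2D(name + "_pw", self.c, cout, 1, 1, "same", False), self.t)
        self.c = cout
        return self.t

    def bn(self, name, eps=1e-3):
        self.t = self.g.add(BatchNorm(name, self.c, eps), self.t)
        return self.t

    def act(self, name, kind="relu"):
        self.t = self.g.add(Activation(name, kind), self.t)
        return self.t

    def zeropad(self, name, pads):
        self.t = self.g.add(ZeroPad(name, pads), self.t)
        return self.t

    def maxpool(self, name, k, s, pad="valid"):
        self.t = self.g.add(MaxPool(name, k, s, pad), self.t)
        return self.t

    def avgpool(self, name, k, s, pad="valid"):
        self.t = self.g.add(AvgPool(name, k, s, pad), self.t)
        return self.t

    def gap(self, name="avg_pool"):
        self.t = self.g.add(GlobalAvgPool(name), self.t)
        return self.t

    def add_from(self, name, *tensors):
        self.t = self.g.add(Add(name), *tensors)
        return self.t

    def concat_from(self, name, *tensors):
        self.t = self.g.add(Concat(name), *tensors)
        self.c = self.g.shape(self.t)[-1]
        return self.t

    def at(self, tensor):
        self.t = tensor
        self.c = self.g.shape(tensor)[-1]
        return self


def _densenet201(size: int) -> Graph:
    g = Graph((size, size, 3))
    b = _B(g)
    growth, eps = 32, 1.001e-5
    b.zeropad("stem_pad", ((3, 3), (3, 3)))
    b.conv("conv1_conv", 64, 7, 2, pad="valid", bias=False)
    b.bn("conv1_bn", eps)
    b.act("conv1_relu")
    b.zeropad("pool1_pad", ((1, 1), (1, 1)))
    b.maxpool("pool1", 3, 2)

    def dense_layer(prefix):
        entry, centry = b.t, b.c
        b.bn(f"{prefix}_0_bn", eps)
        b.act(f"{prefix}_0_relu")
        b.conv(f"{prefix}_1_conv", 4 * growth, 1, bias=False)
        b.bn(f"{prefix}_1_bn", eps)
        b.act(f"{prefix}_1_relu")
        b.conv(f"{prefix}_2_conv", growth, 3, bias=False)
        b.concat_from(f"{prefix}_concat", entry, b.t)

    def transition(prefix):
        b.bn(f"{prefix}_bn", eps)
        b.act(f"{prefix}_relu")
        b.conv(f"{prefix}_conv", b.c // 2, 1, bias=False)
        b.avgpool(f"{prefix}_pool", 2, 2)

    for block_idx, n_layers in enumerate([6, 12, 48, 32], start=2):
        for i in range(1, n_layers + 1):
            dense_layer(f"conv{block_idx}_block{i}")
        if block_idx < 5:
            transition(f"pool{block_idx}")
    b.bn("bn", eps)
    b.act("relu")
    b.gap()
    return g


def _resnet152v2(size: int) -> Graph:
    g = Graph((size, size, 3))
    b = _B(g)
    eps = 1.001e-5
    b.zeropad("conv1_pad", ((3, 3), (3, 3)))
    b.conv("conv1_conv", 64, 7, 2, pad="valid", bias=True)
    b.zeropad("pool1_pad", ((1, 1), (1, 1)))
    b.maxpool("pool1_pool", 3, 2)

    def block(prefix, f, stride=1, conv_shortcut=False):
        entry = b.t
        b.bn(f"{prefix}_preact_bn", eps)
        b.act(f"{prefix}_preact_relu")
        preact = b.t
        if conv_shortcut:
            shortcut = b.conv(f"{prefix}_0_conv", 4 * f, 1, stride, bias=True)
            b.at(preact)
        elif stride > 1:
            b.at(entry)
            shortcut = b.maxpool(f"{prefix}_0_pool", 1, stride)
            b.at(preact)
        else:
            shortcut = entry
            b.at(preact)
        b.conv(f"{prefix}_1_conv", f, 1, 1, bias=False)
        b.bn(f"{prefix}_1_bn", eps)
        b.act(f"{prefix}_1_relu")
        b.zeropad(f"{prefix}_2_pad", ((1, 1), (1, 1)))
        b.conv(f"{prefix}_2_conv", f, 3, stride, pad="valid", bias=False)
        b.bn(f"{prefix}_2_bn", eps)
        b.act(f"{prefix}_2_relu")
        b.conv(f"{prefix}_3_conv", 4 * f, 1, bias=True)
        b.add_from(f"{prefix}_out", shortcut, b.t)
        b.at(b.t)

    for stack_idx, (f, blocks, stride1) in enumerate(
        [(64, 3, 2), (128, 8, 2), (256, 36, 2), (512, 3, 1)], start=2
    ):
        block(f"conv{stack_idx}_block1", f, conv_shortcut=True)
        for i in range(2, blocks):
            block(f"conv{stack_idx}_block{i}", f)
        block(f"conv{stack_idx}_block{blocks}", f, stride=stride1)
    b.bn("post_bn", eps)
    b.act("post_relu")
    b.gap()
    return g


def _xception(size: int) -> Graph:
    g = Graph((size, size, 3))
    b = _B(g)
    b.conv("block1_conv1", 32, 3, 2, pad="valid", bias=False)
    b.bn("block1_conv1_bn")
    b.act("block1_conv1_act")
    b.conv("block1_conv2", 64, 3, pad="valid", bias=False)
    b.bn("block1_conv2_bn")
    b.act("block1_conv2_act")

    def entry_block(prefix, cout, first_relu=True):
        entry, centry = b.t, b.c
        b.conv(f"{prefix}_shortcut_conv", cout, 1, 2, bias=False)
        b.bn(f"{prefix}_shortcut_bn")
        residual = b.t
        b.at(entry)
        if first_relu:
            b.act(f"{prefix}_sepconv1_act")
        b.sepconv(f"{prefix}_sepconv1", cout, 3)
        b.bn(f"{prefix}_sepconv1_bn")
        b.act(f"{prefix}_sepconv2_act")
        b.sepconv(f"{prefix}_sepconv2", cout, 3)
        b.bn(f"{prefix}_sepconv2_bn")
        b.maxpool(f"{prefix}_pool", 3, 2, pad="same")
        b.add_from(f"{prefix}_add", b.t, residual)
        b.at(b.t)

    entry_block("block2", 128, first_relu=False)
    entry_block("block3", 256)
    entry_block("block4", 728)
    for i in range(5, 13):
        entry = b.t
        for j in (1, 2, 3):
            b.act(f"block{i}_sepconv{j}_act")
            b.sepconv(f"block{i}_sepconv{j}", 728, 3)
            b.bn(f"block{i}_sepconv{j}_bn")
        b.add_from(f"block{i}_add", b.t, entry)
        b.at(b.t)
    # exit flow
    entry = b.t
    b.conv("block13_shortcut_conv", 1024, 1, 2, bias=False)
    b.bn("block13_shortcut_bn")
    residual = b.t
    b.at(entry)
    b.act("block13_sepconv1_act")
    b.sepconv("block13_sepconv1", 728, 3)
    b.bn("block13_sepconv1_bn")
    b.act("block13_sepconv2_act")
    b.sepconv("block13_sepconv2", 1024, 3)
    b.bn("block13_sepconv2_bn")
    b.maxpool("block13_pool", 3, 2, pad="same")
    b.add_from("block13_add", b.t, residual)
    b.at(b.t)
    b.sepconv("block14_sepconv1", 1536, 3)
    b.bn("block14_sepconv1_bn")
    b.act("block14_sepconv1_act")
    b.sepconv("block14_sepconv2", 2048, 3)
    b.bn("block14_sepconv2_bn")
    b.act("block14_sepconv2_act")
    b.gap()
    return g


def _mobilenetv2(size: int) -> Graph:
    g = Graph((size, size, 3))
    b = _B(g)
    eps = 1e-3
    b.zeropad("conv1_pad", ((0, 1), (0, 1)))
    b.conv("conv1", 32, 3, 2, pad="valid", bias=False)
    b.bn("bn_conv1", eps)
    b.act("conv1_relu", "relu6")

    block_id = 0

    def inverted_residual(cout, stride, expansion):
        nonlocal block_id
        prefix = f"block_{block_id}"
        cin = b.c
        entry = b.t
        if expansion != 1:
            b.conv(f"{prefix}_expand", expansion * cin, 1, bias=False)
            b.bn(f"{prefix}_expand_bn", eps)
            b.act(f"{prefix}_expand_relu", "relu6")
        if stride == 2:
            b.zeropad(f"{prefix}_pad", ((0, 1), (0, 1)))
            b.dwconv(f"{prefix}_depthwise", 3, 2, pad="valid")
        else:
            b.dwconv(f"{prefix}_depthwise", 3, 1)
        b.bn(f"{prefix}_depthwise_bn", eps)
        b.act(f"{prefix}_depthwise_relu", "relu6")
        b.conv(f"{prefix}_project", cout, 1, bias=False)
        b.bn(f"{prefix}_project_bn", eps)
        if stride == 1 and cin == cout:
            b.add_from(f"{prefix}_add", entry, b.t)
            b.at(b.t)
        block_id += 1

    for t, c, n, s in [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2),
                       (6, 64, 4, 2), (6, 96, 3, 1), (6, 160, 3, 2),
                       (6, 320, 1, 1)]:
        for i in range(n):
            inverted_residual(c, s if i == 0 else 1, t)
    b.conv("conv_1", 1280, 1, bias=False)
    b.bn("conv_1_bn", eps)
    b.act("out_relu", "relu6")
    b.gap()
    return g


def _tinycnn(size: int) -> Graph:
    # inference-mode twin of the trainable net in tinynet.py (same layout)
    g = Graph((size, size, 3))
    b = _B(g)
    for i, c in enumerate([16, 32, 64, 128], start=1):
        b.conv(f"conv{i}", c, 3, bias=False)
        b.bn(f"bn{i}")
        b.act(f"relu{i}")
        b.maxpool(f"pool{i}", 2, 2)
    b.gap()
    return g


_BUILDERS = {
    "densenet201": _densenet201,
    "resnet152v2": _resnet152v2,
    "xception": _xception,
    "mobilenetv2": _mobilenetv2,
    "tinycnn": _tinycnn,
}


def build_backbone(name: str, input_size: int | None = None) -> Graph:
    """Build the named backbone graph ending at global average pooling."""
    if name not in _BUILDERS:
        raise ValueError(
            f"unknown backbone {name!r}; valid names: {sorted(_BUILDERS)}"
        )
    if input_size is None:
        input_size = BACKBONES[name][0]
    return _BUILDERS[name](input_size)


def feature_width(name: str) -> int:
    """Width of the pooled feature vector the heads attach to."""
    if name not in BACKBONES:
        raise ValueError(
            f"unknown backbone {name!r}; valid names: {sorted(BACKBONES)}"
        )
    return BACKBONES[name][1]
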