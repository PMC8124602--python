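"""Build multiple-output regression CNNs and count their parameters.

A regressor is a named backbone with its classification layer removed,
global average pooling retained, and six parallel single-node linear dense
heads (one per target, in label order) attached to the pooled features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pigdepth.labels import LABEL_NAMES, N_TARGETS
from pigdepth.nn.backbones import BACKBONES, build_backbone, feature_width
from pigdepth.nn.engine import Concat, Dense, Graph
from pigdepth.nn.tinynet import TinyNet

__all__ = [
    "ModelSpec",
    "ParameterCount",
    "build_regressor",
    "count_parameters",
    "head_parameter_count",
]

#: Required input sizes for the reference backbones.
_FIXED_INPUT_SIZES = {
    "densenet201": 224,
    "mobilenetv2": 224,
    "resnet152v2": 224,
    "xception": 299,
}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description of a multiple-output regressor.

    Input is a 3-channel tensor; the single-channel gray image is
    replicated across channels and normalized to [-1, 1] inside the model
    (``(x - input_offset) / input_scale``).
    """

    backbone_name: str
    input_size: int | None = None
    n_outputs: int = N_TARGETS
    pretrained: bool = False
    seed: int = 0
    head_w_init: str = "glorot"  # or "zeros"
    head_bias_init: tuple[float, ...] | None = None
    input_offset: float = 127.5
    input_scale: float = 127.5

    def __post_init__(self):
        if self.backbone_name not in BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone_name!r}; valid names: "
                f"{sorted(BACKBONES)}"
            )
        if self.n_outputs != N_TARGETS:
            raise ValueError(f"n_outputs must be {N_TARGETS}, got {self.n_outputs}")
        fixed = _FIXED_INPUT_SIZES.get(self.backbone_name)
        if fixed is not None and self.input_size not in (None, fixed):
            raise ValueError(
                f"{self.backbone_name} requires input_size {fixed}, "
                f"got {self.input_size}"
            )

    @property
    def resolved_input_size(self) -> int:
        if self.input_size is not None:
            return self.input_size
        return BACKBONES[self.backbone_name][0]


@dataclass(frozen=True)
class ParameterCount:
    total: int
    trainable: int

    def __post_init__(self):
        if not (0 < self.trainable <= self.total):
            raise ValueError(
                f"require 0 < trainable <= total, got {self.trainable}/{self.total}"
            )


def head_parameter_count(backbone_name: str) -> int:
    """Parameters contributed by the six heads: 6 * (feature_width + 1)."""
    return N_TARGETS * (feature_width(backbone_name) + 1)


class StaticRegressor:
    """Inference-only regressor around a static backbone graph.

    ``predict`` maps gray images (n, S, S) to (n, 6) estimates ordered as
    LABEL_NAMES. Training this class is not supported in the NumPy engine;
    use the ``tinycnn`` backbone for end-to-end training.
    """

    trainable = False

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        size = spec.resolved_input_size
        self.graph = build_backbone(spec.backbone_name, size)
        feats = self.graph.output
        f = feature_width(spec.backbone_name)
        bias = spec.head_bias_init or (0.0,) * N_TARGETS
        heads = []
        for i, nm in enumerate(LABEL_NAMES):
            d = Dense(f"head_{nm}", f, 1, use_bias=True, w_init=spec.head_w_init)
            d.b.value[:] = bias[i]
            heads.append(self.graph.add(d, feats))
        self.graph.add(Concat("outputs"), *heads)
        self.input_size = size

    def parameters(self):
        return self.graph.parameters()

    def predict(self, images, batch_size: int = 8):
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 4 and x.shape[-1] == 1:
            x = x[..., 0]
        if x.shape[1:] != (self.input_size, self.input_size):
            raise ValueError(
                f"expected gray images (n, {self.input_size}, {self.input_size}), "
                f"got {x.shape}"
            )
        x = (x - self.spec.input_offset) / self.spec.input_scale
        x = np.repeat(x[..., None], 3, axis=-1)
        outs = [
            self.graph.forward(x[i : i + batch_size])
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)


class TinyRegressor(TinyNet):
    """Trainable regressor: TinyNet with a ModelSpec attached."""

    trainable = True

    def __init__(self, spec: ModelSpec):
        bias = spec.head_bias_init
        super().__init__(
            input_size=spec.resolved_input_size,
            seed=spec.seed,
            head_w_init=spec.head_w_init,
            head_bias_init=None if bias is None else np.asarray(bias),
            head_names=LABEL_NAMES,
            input_offset=spec.input_offset,
            input_scale=spec.input_scale,
        )
        self.spec = spec


def build_regressor(spec: ModelSpec):
    """Construct the regressor described by ``spec``.

    The ``tinycnn`` backbone returns a trainable model; the reference
    backbones return inference/counting models (no autodiff backend is
    available in this engine). ImageNet-pretrained initialization is not
    available offline.
    """
    if spec.pretrained:
        raise NotImplementedError(
            "pretrained initialization requires downloadable weights, which "
            "are unavailable in this offline build; use pretrained=False"
        )
    if spec.backbone_name == "tinycnn":
        return TinyRegressor(spec)
    return StaticRegressor(spec)


def count_parameters(model) -> ParameterCount:
    """Count all parameters of a built regressor.

    ``total`` includes every weight, bias and batch-normalization
    statistic; ``trainable`` excludes the batch-normalization moving
    means/variances.
    """
    params = model.parameters()
    total = sum(p.size for p in params)
    trainable = sum(p.size for p in params if p.trainable)
    return ParameterCount(total=total, trainable=trainable)
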