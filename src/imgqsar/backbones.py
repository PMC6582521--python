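"""Convolutional feature-extraction backbones.

Faithful layer-by-layer implementations of the four classic ImageNet
architecture families used for transfer learning on compound images: AlexNet,
VGG-19 with batch normalization, ResNet-152, and DenseNet-201. Each
constructor returns the feature-extraction subgraph (everything up to, but not
including, the classification head) plus the flattened feature dimensionality
its classifier consumes.

Weights are randomly initialized (He); this environment trains from scratch or
uses the backbones as frozen random feature extractors.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    AdaptiveAvgPool2d,
    AvgPool2d,
    BatchNorm2d,
    Concat,
    Conv2d,
    Flatten,
    MaxPool2d,
    ReLU,
    Residual,
    Sequential,
)

#: Flattened feature dimension each backbone presents to its classifier.
FEATURE_DIMS = {
    "alexnet": 256 * 6 * 6,
    "vgg19bn": 512 * 7 * 7,
    "resnet152": 2048,
    "densenet201": 1920,
}

BACKBONE_IDS = tuple(FEATURE_DIMS)


def _alexnet(rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(3, 64, 11, rng, stride=4, pad=2),
        ReLU(),
        MaxPool2d(3, 2),
        Conv2d(64, 192, 5, rng, pad=2),
        ReLU(),
        MaxPool2d(3, 2),
        Conv2d(192, 384, 3, rng, pad=1),
        ReLU(),
        Conv2d(384, 256, 3, rng, pad=1),
        ReLU(),
        Conv2d(256, 256, 3, rng, pad=1),
        ReLU(),
        MaxPool2d(3, 2),
        AdaptiveAvgPool2d(6, 6),
        Flatten(),
    )


_VGG19_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


def _vgg19bn(rng: np.random.Generator) -> Sequential:
    layers: list = []
    in_ch = 3
    for v in _VGG19_CFG:
        if v == "M":
            layers.append(MaxPool2d(2, 2))
        else:
            layers += [Conv2d(in_ch, v, 3, rng, pad=1), BatchNorm2d(v), ReLU()]
            in_ch = v
    layers += [AdaptiveAvgPool2d(7, 7), Flatten()]
    return Sequential(*layers)


def _bottleneck(
    rng: np.random.Generator, in_ch: int, width: int, stride: int
) -> Residual:
    out_ch = width * 4
    branch = Sequential(
        Conv2d(in_ch, width, 1, rng, bias=False),
        BatchNorm2d(width),
        ReLU(),
        Conv2d(width, width, 3, rng, stride=stride, pad=1, bias=False),
        BatchNorm2d(width),
        ReLU(),
        Conv2d(width, out_ch, 1, rng, bias=False),
        BatchNorm2d(out_ch),
    )
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = Sequential(
            Conv2d(in_ch, out_ch, 1, rng, stride=stride, bias=False),
            BatchNorm2d(out_ch),
        )
    return Residual(branch, shortcut)


def _resnet152(rng: np.random.Generator) -> Sequential:
    layers: list = [
        Conv2d(3, 64, 7, rng, stride=2, pad=3, bias=False),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, 2, pad=1),
    ]
    in_ch = 64
    for width, blocks, stride in [(64, 3, 1), (128, 8, 2), (256, 36, 2), (512, 3, 2)]:
        for b in range(blocks):
            layers.append(_bottleneck(rng, in_ch, width, stride if b == 0 else 1))
            in_ch = width * 4
    layers += [AdaptiveAvgPool2d(1, 1), Flatten()]
    return Sequential(*layers)


def _dense_layer(rng: np.random.Generator, in_ch: int, growth: int) -> Concat:
    return Concat(
        Sequential(
            BatchNorm2d(in_ch),
            ReLU(),
            Conv2d(in_ch, 4 * growth, 1, rng, bias=False),
            BatchNorm2d(4 * growth),
            ReLU(),
            Conv2d(4 * growth, growth, 3, rng, pad=1, bias=False),
        )
    )


def _densenet201(rng: np.random.Generator) -> Sequential:
    growth = 32
    layers: list = [
        Conv2d(3, 64, 7, rng, stride=2, pad=3, bias=False),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, 2, pad=1),
    ]
    ch = 64
    block_cfg = [6, 12, 48, 32]
    for bi, n_layers in enumerate(block_cfg):
        for _ in range(n_layers):
            layers.append(_dense_layer(rng, ch, growth))
            ch += growth
        if bi < len(block_cfg) - 1:  # transition halves channels and size
            layers += [
                BatchNorm2d(ch),
                ReLU(),
                Conv2d(ch, ch // 2, 1, rng, bias=False),
                AvgPool2d(2),
            ]
            ch //= 2
    layers += [BatchNorm2d(ch), ReLU(), AdaptiveAvgPool2d(1, 1), Flatten()]
    return Sequential(*layers)


_BUILDERS = {
    "alexnet": _alexnet,
    "vgg19bn": _vgg19bn,
    "resnet152": _resnet152,
    "densenet201": _densenet201,
}


def build_backbone(backbone_id: str, rng: np.random.Generator) -> tuple[Sequential, int]:
    """Construct a backbone feature extractor; returns (network, feature_dim)."""
    if backbone_id not in _BUILDERS:
        raise ValueError(
            f"unknown backbone {backbone_id!r}; choose from {sorted(_BUILDERS)}"
        )
    return _BUILDERS[backbone_id](rng), FEATURE_DIMS[backbone_id]
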