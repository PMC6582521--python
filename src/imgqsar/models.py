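"""Model families: ConvNet regressors, fingerprint DNNs, Random Forests.

A ConvNet regressor is a pretrained-style convolutional backbone whose
classifier is replaced by a regression head with no output nonlinearity:
either a single linear layer ("standard") or a five-layer fully-connected
stack of widths 4096/1000/200/100/n_tasks with ReLU and 50% dropout on the
hidden layers ("extended"). The DNN is a 60/20/10 ReLU network with 10%
dropout on Morgan fingerprints; the RF baseline is a 100-tree regression
forest at library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from . import nn
from .backbones import BACKBONE_IDS, build_backbone
from .chem_data import FINGERPRINT_LENGTHS

HEADS = ("standard", "extended")
EXTENDED_HEAD_WIDTHS = [4096, 1000, 200, 100]


@dataclass
class ConvNetSpec:
    """Architecture of an image-regression network.

    ``pretrained=True`` would load ImageNet weights; no offline weight source
    exists in this distribution, so backbones start from He random
    initialization (``pretrained=False``).
    """

    backbone_id: str = "alexnet"
    head: str = "standard"
    n_tasks: int = 1
    head_widths: list[int] = field(default_factory=lambda: list(EXTENDED_HEAD_WIDTHS))
    head_dropout: float = 0.5
    final_hidden_relu: bool = True
    pretrained: bool = False
    freeze_backbone: bool = False

    def __post_init__(self) -> None:
        if self.backbone_id not in BACKBONE_IDS:
            raise ValueError(
                f"unknown backbone {self.backbone_id!r}; choose from {BACKBONE_IDS}"
            )
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        if self.n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")


@dataclass
class DNNSpec:
    """Fully-connected network on fingerprints: input -> 60 -> 20 -> 10 -> 1."""

    input_dim: int = 2048
    hidden_widths: list[int] = field(default_factory=lambda: [60, 20, 10])
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.input_dim not in FINGERPRINT_LENGTHS:
            raise ValueError(
                f"input_dim must be a supported fingerprint length {FINGERPRINT_LENGTHS}"
            )


@dataclass
class RFSpec:
    """Random Forest regression baseline; defaults except n_trees=100."""

    n_trees: int = 100

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class ConvNetRegressor:
    """Backbone feature extractor + regression head, trained jointly or frozen.

    The feature-extraction subgraph is identical between standard and extended
    variants of the same backbone seed; only the classifier differs.
    """

    def __init__(self, spec: ConvNetSpec, rng: np.random.Generator):
        if spec.pretrained:
            raise ValueError(
                "pretrained weights are not distributed with this package; "
                "use pretrained=False (random initialization)"
            )
        self.spec = spec
        self.backbone, self.feature_dim = build_backbone(spec.backbone_id, rng)
        self.head = _build_head(spec, self.feature_dim, rng)
        if spec.freeze_backbone:
            self.backbone.freeze()
        self.net = nn.Sequential(self.backbone, self.head)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train)

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.backbone.forward(x, train)

    def forward_head(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(feats, train)

    @property
    def head_param_count(self) -> int:
        return self.head.n_params


def _build_head(spec: ConvNetSpec, feature_dim: int, rng: np.random.Generator) -> nn.Sequential:
    if spec.head == "standard":
        return nn.Sequential(nn.Linear(feature_dim, spec.n_tasks, rng))
    layers: list[nn.Layer] = []
    widths = [feature_dim] + list(spec.head_widths)
    for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
        layers.append(nn.Linear(a, b, rng))
        if spec.final_hidden_relu or i < len(spec.head_widths) - 1:
            layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.head_dropout, rng))
    layers.append(nn.Linear(widths[-1], spec.n_tasks, rng))
    return nn.Sequential(*layers)


def extended_head_param_count(feature_dim: int, n_tasks: int = 1) -> int:
    """Closed-form parameter count of the extended head (weights + biases)."""
    widths = [feature_dim] + EXTENDED_HEAD_WIDTHS + [n_tasks]
    return sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))


class MLPRegressor:
    """Fingerprint DNN: input -> hidden widths -> 1, ReLU + dropout on hiddens."""

    def __init__(self, spec: DNNSpec, rng: np.random.Generator):
        self.spec = spec
        layers: list[nn.Layer] = []
        widths = [spec.input_dim] + list(spec.hidden_widths)
        for a, b in zip(widths[:-1], widths[1:]):
            layers += [nn.Linear(a, b, rng), nn.ReLU(), nn.Dropout(spec.dropout, rng)]
        layers.append(nn.Linear(widths[-1], 1, rng))
        self.net = nn.Sequential(*layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train)

    @property
    def param_count(self) -> int:
        return self.net.n_params


def build_convnet(spec: ConvNetSpec, seed: int = 0) -> ConvNetRegressor:
    """Construct a ConvNet regressor with a seeded initialization."""
    return ConvNetRegressor(spec, np.random.default_rng(seed))


def build_dnn(spec: DNNSpec, seed: int = 0) -> MLPRegressor:
    """Construct the fingerprint DNN with a seeded initialization."""
    return MLPRegressor(spec, np.random.default_rng(seed))


def build_rf(spec: RFSpec, seed: int = 0) -> RandomForestRegressor:
    """Regression forest with ``n_trees`` estimators, seeded for reproducibility."""
    return RandomForestRegressor(n_estimators=spec.n_trees, random_state=seed)
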