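"""Data splitting, the cyclical step-decay schedule, and training loops.

All three model families (image ConvNets, fingerprint DNNs, Random Forests)
are trained on identical 70/15/15 train/validation/test splits. Networks are
optimized with SGD + Nesterov momentum (0.9) on per-batch mean squared error;
validation RMSE is monitored every epoch for best-epoch checkpointing and
early stopping. The learning rate follows a cyclical annealing schedule:
within each 200-epoch cycle it decays by a fixed factor every ``anneal_step``
epochs and resets to its initial value at the cycle boundary.
"""

from __future__ import annotations

import copy
import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .chem_data import BioactivityDataset, CompoundRecord, fingerprint_matrix
from .evaluation import pearson_r, r_squared
from .imaging import AugmentationPolicy, RenderedImage, augment, normalize_for_backbone
from .models import ConvNetRegressor, ConvNetSpec, DNNSpec, RFSpec, build_dnn, build_rf

#: Hyperparameter grid explored for the networks (values as published, with
#: the learning-rate set de-duplicated to five distinct values).
TABLE_GRID = {
    "lr0": (0.1, 0.01, 0.005, 0.001, 0.0001),
    "decay_rate": (0.1, 0.6),
    "anneal_step": (10, 25),
    "augmentation": (True, False),
    "batch_size": (4, 16, 32),
}


@dataclass
class OptimSpec:
    """Optimization schedule for network training."""

    lr0: float = 0.01
    decay_rate: float = 0.1
    anneal_step: int = 10
    cycle_length: int = 200
    momentum: float = 0.9
    batch_size: int = 16
    max_epochs: int = 600
    early_stop_patience: int = 250
    augmentation: bool = False
    #: Standardize frozen-backbone features to zero mean / unit variance on the
    #: training split before the head (frozen feature-extractor path only).
    standardize_features: bool = False
    #: Start the output layer at the mean-predictor solution (zero weights,
    #: bias = mean training label); early epochs then refine the signal.
    init_output_bias: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.decay_rate < 1.0:
            raise ValueError("decay_rate must lie in (0, 1)")
        if self.anneal_step >= self.cycle_length:
            raise ValueError("anneal_step must be smaller than cycle_length")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("early_stop_patience cannot exceed max_epochs")


#: Paper-scale ("full") and desk-scale ("ci") training presets.
PRESETS = {
    "full": dict(max_epochs=600, early_stop_patience=250, batch_size=16),
    "ci": dict(
        max_epochs=30,
        early_stop_patience=10,
        batch_size=16,
        lr0=0.0001,
        standardize_features=True,
    ),
}

CI_CONVNET_SPEC = ConvNetSpec(
    backbone_id="alexnet", head="standard", freeze_backbone=True, pretrained=False
)


@dataclass
class RunResult:
    """Outcome of one trained model on one split (one factorial-design row)."""

    dataset_id: str
    model_id: str
    batch_size: int
    augmentation: bool
    replicate: int
    seed: int
    predictions: dict[str, np.ndarray]
    observed: dict[str, np.ndarray]
    rmse_test: float
    rmse_val: float
    r2: float
    pearson: float
    rmse_test_per_task: list[float]
    epochs_run: int

    @property
    def residuals(self) -> dict[str, np.ndarray]:
        return {
            cid: self.observed[cid] - self.predictions[cid] for cid in self.predictions
        }

    def scalar_predictions(self, task: int = 0) -> dict[str, float]:
        return {cid: float(v[task]) for cid, v in self.predictions.items()}

    def scalar_observed(self, task: int = 0) -> dict[str, float]:
        return {cid: float(v[task]) for cid, v in self.observed.items()}


def split_dataset(dataset: BioactivityDataset, seed: int) -> BioactivityDataset:
    """Random 70/15/15 train/validation/test split.

    Sizes: train = floor(0.70 n), validation = floor(0.15 n), test = the
    remainder. The same split is reused for every model family.
    """
    n = len(dataset.records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.floor(0.70 * n)
    n_val = math.floor(0.15 * n)
    out = copy.deepcopy(dataset)
    ids = [out.records[i].compound_id for i in order]
    out.split = {}
    for i, cid in enumerate(ids):
        if i < n_train:
            out.split[cid] = "train"
        elif i < n_train + n_val:
            out.split[cid] = "validation"
        else:
            out.split[cid] = "test"
    return out


def lr_at(epoch: int, spec: OptimSpec) -> float:
    """Learning rate at ``epoch`` under the cyclical step-decay schedule."""
    phase = epoch % spec.cycle_length
    return spec.lr0 * spec.decay_rate ** (phase // spec.anneal_step)


def _label_matrix(
    records: list[CompoundRecord], target_ids: list[str]
) -> np.ndarray:
    """(n, n_tasks) label matrix with NaN for unobserved (compound, task)."""
    y = np.full((len(records), len(target_ids)), np.nan)
    for i, r in enumerate(records):
        for j, tid in enumerate(target_ids):
            if tid in r.activities:
                y[i, j] = r.activities[tid]
    return y


def _masked_mse_grad(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over observed entries only, plus its gradient."""
    mask = ~np.isnan(y)
    n_obs = int(mask.sum())
    if n_obs == 0:
        return 0.0, np.zeros_like(pred)
    diff = np.where(mask, pred - np.where(mask, y, 0.0), 0.0)
    loss = float((diff**2).sum() / n_obs)
    return loss, 2.0 * diff / n_obs


def _eval_rmse(pred: np.ndarray, y: np.ndarray) -> float:
    mask = ~np.isnan(y)
    return float(np.sqrt(np.mean((pred[mask] - y[mask]) ** 2)))


def _init_output_bias(net: nn.Layer, y_train: np.ndarray) -> None:
    """Start the output layer's bias at the mean training label per task.

    Standard regression-head initialization: the network begins at the
    mean-predictor solution instead of zero, so early epochs refine the
    signal rather than relearn the label offset.
    """
    linears = [l for l in _iter_layers(net) if isinstance(l, nn.Linear)]
    if not linears or not linears[-1].b.trainable:
        return
    means = np.nanmean(y_train, axis=0)
    linears[-1].b.value[...] = np.where(np.isfinite(means), means, 0.0)
    linears[-1].W.value *= 0.0


def _iter_layers(layer: nn.Layer):
    yield layer
    for attr in ("layers",):
        for sub in getattr(layer, attr, []):
            yield from _iter_layers(sub)
    for attr in ("branch", "shortcut"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, nn.Layer):
            yield from _iter_layers(sub)


class _Trainer:
    """Shared SGD loop: batching, schedule, checkpointing, early stopping."""

    def __init__(
        self,
        net: nn.Layer,
        optim_spec: OptimSpec,
        rng: np.random.Generator,
        forward_train,
        forward_eval,
    ):
        self.net = net
        self.spec = optim_spec
        self.rng = rng
        self.forward_train = forward_train
        self.forward_eval = forward_eval
        self.optimizer = nn.SGDNesterov(net.params(), optim_spec.momentum)
        self.log: list[dict] = []

    def fit(self, train_data, y_train, val_data, y_val) -> tuple[int, float]:
        if self.spec.init_output_bias:
            _init_output_bias(self.net, y_train)
        best_state = nn.get_state(self.net)
        best_val = np.inf
        since_best = 0
        epochs_run = 0
        n = y_train.shape[0]
        for epoch in range(self.spec.max_epochs):
            lr = lr_at(epoch, self.spec)
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.spec.batch_size):
                idx = order[start : start + self.spec.batch_size]
                pred = self.forward_train(train_data, idx, epoch)
                loss, grad = _masked_mse_grad(pred, y_train[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} (lr={lr:g}); "
                        "reduce the learning rate"
                    )
                self.optimizer.zero_grad()
                self.net.backward(grad)
                self.optimizer.step(lr)
                epoch_loss += loss * len(idx)
            val_pred = self.forward_eval(val_data)
            val_rmse = _eval_rmse(val_pred, y_val)
            self.log.append(
                {"epoch": epoch, "lr": lr, "train_loss": epoch_loss / n, "val_rmse": val_rmse}
            )
            epochs_run = epoch + 1
            if val_rmse < best_val:
                best_val = val_rmse
                best_state = nn.get_state(self.net)
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.spec.early_stop_patience:
                    break
        nn.set_state(self.net, best_state)
        return epochs_run, float(best_val)


def _finalize(
    dataset_id: str,
    model_id: str,
    optim_spec: OptimSpec,
    seed: int,
    replicate: int,
    test_records: list[CompoundRecord],
    y_test: np.ndarray,
    pred_test: np.ndarray,
    rmse_val: float,
    epochs_run: int,
) -> RunResult:
    mask = ~np.isnan(y_test)
    per_task = [
        _eval_rmse(pred_test[:, j : j + 1], y_test[:, j : j + 1])
        for j in range(y_test.shape[1])
        if mask[:, j].any()
    ]
    obs_flat = y_test[mask]
    pred_flat = pred_test[mask]
    return RunResult(
        dataset_id=dataset_id,
        model_id=model_id,
        batch_size=optim_spec.batch_size,
        augmentation=optim_spec.augmentation,
        replicate=replicate,
        seed=seed,
        predictions={r.compound_id: pred_test[i] for i, r in enumerate(test_records)},
        observed={r.compound_id: y_test[i] for i, r in enumerate(test_records)},
        rmse_test=_eval_rmse(pred_test, y_test),
        rmse_val=rmse_val,
        r2=r_squared(obs_flat, pred_flat) if np.std(obs_flat) > 0 and np.std(pred_flat) > 0 else 0.0,
        pearson=pearson_r(obs_flat, pred_flat) if np.std(obs_flat) > 0 and np.std(pred_flat) > 0 else 0.0,
        rmse_test_per_task=per_task,
        epochs_run=epochs_run,
    )


def train_convnet(
    dataset: BioactivityDataset,
    images: dict[str, RenderedImage],
    conv_spec: ConvNetSpec,
    optim_spec: OptimSpec,
    seed: int,
    dataset_id: str = "dataset",
    replicate: int = 0,
) -> RunResult:
    """Train an image ConvNet regressor and score it on the test split.

    With a frozen backbone and augmentation disabled, backbone features are
    computed once and the head is trained on the cached features; otherwise
    every epoch forwards (possibly augmented) images through the full network.
    """
    for split_label in ("train", "validation", "test"):
        if not dataset.subset(split_label):
            raise ValueError(f"empty {split_label} split")
    rng = np.random.default_rng(seed)
    model = ConvNetRegressor(replace(conv_spec, n_tasks=len(dataset.target_ids) if conv_spec.n_tasks > 1 else conv_spec.n_tasks), rng)
    target_ids = dataset.target_ids[: model.spec.n_tasks]

    splits = {s: dataset.subset(s) for s in ("train", "validation", "test")}
    ys = {s: _label_matrix(recs, target_ids) for s, recs in splits.items()}
    pixel_sets = {
        s: [images[r.compound_id].pixels for r in recs] for s, recs in splits.items()
    }

    policy = AugmentationPolicy(enabled=optim_spec.augmentation)
    frozen_fast_path = model.spec.freeze_backbone and not optim_spec.augmentation

    def tensors(pixels_list, do_augment: bool):
        arr = []
        for px in pixels_list:
            if do_augment:
                px = augment(px, policy, rng)
            arr.append(normalize_for_backbone(px))
        return np.stack(arr)

    def features_chunked(pixels_list, chunk: int = 16):
        # bound peak memory: early conv activations are large per image
        parts = []
        for start in range(0, len(pixels_list), chunk):
            batch = tensors(pixels_list[start : start + chunk], False)
            parts.append(model.forward_features(batch))
        return np.concatenate(parts, axis=0)

    if frozen_fast_path:
        feats = {s: features_chunked(pixel_sets[s]) for s in splits}
        if optim_spec.standardize_features:
            mu = feats["train"].mean(axis=0)
            sd = feats["train"].std(axis=0)
            sd[sd == 0] = 1.0
            feats = {s: (f - mu) / sd for s, f in feats.items()}
        trainer = _Trainer(
            model.head,
            optim_spec,
            rng,
            forward_train=lambda data, idx, epoch: model.forward_head(data[idx], train=True),
            forward_eval=lambda data: model.forward_head(data, train=False),
        )
        epochs_run, best_val = trainer.fit(
            feats["train"], ys["train"], feats["validation"], ys["validation"]
        )
        pred_test = model.forward_head(feats["test"], train=False)
    else:
        train_px = pixel_sets["train"]
        val_x = tensors(pixel_sets["validation"], False)
        test_x = tensors(pixel_sets["test"], False)

        def forward_train(data, idx, epoch):
            batch = tensors([data[i] for i in idx], optim_spec.augmentation)
            return model.forward(batch, train=True)

        trainer = _Trainer(
            model.net,
            optim_spec,
            rng,
            forward_train=forward_train,
            forward_eval=lambda data: model.forward(data, train=False),
        )
        epochs_run, best_val = trainer.fit(
            train_px, ys["train"], val_x, ys["validation"]
        )
        pred_test = model.forward(test_x, train=False)

    result = _finalize(
        dataset_id,
        f"{model.spec.backbone_id}-{model.spec.head}",
        optim_spec,
        seed,
        replicate,
        splits["test"],
        ys["test"],
        pred_test,
        best_val,
        epochs_run,
    )
    result.log = trainer.log  # type: ignore[attr-defined]
    return result


def train_multitask(
    dataset: BioactivityDataset,
    images: dict[str, RenderedImage],
    conv_spec: ConvNetSpec,
    optim_spec: OptimSpec,
    seed: int,
    dataset_id: str = "dataset",
    replicate: int = 0,
) -> RunResult:
    """Multi-task ConvNet over all dataset targets with masked squared error.

    The loss averages squared errors over observed (compound, task) pairs
    only; a task absent from a batch contributes exactly zero gradient.
    Per-task test RMSEs are reported separately.
    """
    n_tasks = len(dataset.target_ids)
    if n_tasks < 2:
        raise ValueError("multi-task training needs >= 2 targets")
    for tid in dataset.target_ids:
        if not any(tid in r.activities for r in dataset.records):
            raise ValueError(f"task {tid!r} has no observed labels")
    return train_convnet(
        dataset,
        images,
        replace(conv_spec, n_tasks=n_tasks),
        optim_spec,
        seed,
        dataset_id=dataset_id,
        replicate=replicate,
    )


def train_dnn(
    dataset: BioactivityDataset,
    dnn_spec: DNNSpec,
    seed: int,
    optim_spec: OptimSpec | None = None,
    dataset_id: str = "dataset",
    replicate: int = 0,
    fp_radius: int = 2,
) -> RunResult:
    """Train the fingerprint DNN: batches of 15% of the training set,
    up to 2000 epochs with patience 200, SGD + Nesterov momentum."""
    splits = {s: dataset.subset(s) for s in ("train", "validation", "test")}
    for s, recs in splits.items():
        if not recs:
            raise ValueError(f"empty {s} split")
    target_ids = dataset.target_ids[:1]
    ys = {s: _label_matrix(recs, target_ids) for s, recs in splits.items()}
    xs = {
        s: fingerprint_matrix(recs, radius=fp_radius, n_bits=dnn_spec.input_dim)
        for s, recs in splits.items()
    }
    n_train = len(splits["train"])
    if optim_spec is None:
        optim_spec = OptimSpec(max_epochs=2000, early_stop_patience=200)
    optim_spec = replace(optim_spec, batch_size=math.ceil(0.15 * n_train))

    rng = np.random.default_rng(seed)
    model = build_dnn(dnn_spec, seed)
    trainer = _Trainer(
        model.net,
        optim_spec,
        rng,
        forward_train=lambda data, idx, epoch: model.forward(data[idx], train=True),
        forward_eval=lambda data: model.forward(data, train=False),
    )
    epochs_run, best_val = trainer.fit(
        xs["train"], ys["train"], xs["validation"], ys["validation"]
    )
    pred_test = model.forward(xs["test"], train=False)
    result = _finalize(
        dataset_id,
        f"dnn-{dnn_spec.input_dim}",
        optim_spec,
        seed,
        replicate,
        splits["test"],
        ys["test"],
        pred_test,
        best_val,
        epochs_run,
    )
    result.log = trainer.log  # type: ignore[attr-defined]
    return result


def train_rf(
    dataset: BioactivityDataset,
    rf_spec: RFSpec,
    fp_bits: int,
    seed: int,
    dataset_id: str = "dataset",
    replicate: int = 0,
    fp_radius: int = 2,
) -> RunResult:
    """Fit the Random Forest baseline on training-split fingerprints.

    The validation split is deliberately unused (no hyperparameters are
    tuned); it is kept in the split so all model families share one test set.
    """
    splits = {s: dataset.subset(s) for s in ("train", "validation", "test")}
    if not splits["train"] or not splits["test"]:
        raise ValueError("RF training needs non-empty train and test splits")
    target_ids = dataset.target_ids[:1]
    ys = {s: _label_matrix(recs, target_ids) for s, recs in splits.items()}
    xs = {
        s: fingerprint_matrix(recs, radius=fp_radius, n_bits=fp_bits)
        for s, recs in splits.items()
        if recs
    }
    model = build_rf(rf_spec, seed)
    model.fit(xs["train"], ys["train"][:, 0])
    pred_test = model.predict(xs["test"])[:, None]
    result = _finalize(
        dataset_id,
        f"rf-{fp_bits}",
        OptimSpec(),
        seed,
        replicate,
        splits["test"],
        ys["test"],
        pred_test,
        float("nan"),
        0,
    )
    result.batch_size = 0  # not applicable to forests
    result.model = model  # type: ignore[attr-defined]
    return result


def grid_search(
    dataset: BioactivityDataset,
    images: dict[str, RenderedImage],
    conv_spec: ConvNetSpec,
    seed: int,
    grid: dict | None = None,
    base_optim: OptimSpec | None = None,
    dataset_id: str = "dataset",
) -> tuple[OptimSpec, list[RunResult]]:
    """Train one ConvNet per grid point; pick minimal validation RMSE.

    Ties break by enumeration order (lr, decay, step, augmentation, batch).
    """
    grid = dict(TABLE_GRID if grid is None else grid)
    base = base_optim if base_optim is not None else OptimSpec()
    keys = [k for k in ("lr0", "decay_rate", "anneal_step", "augmentation", "batch_size") if k in grid]
    if not keys or any(len(grid[k]) == 0 for k in keys):
        raise ValueError("empty grid")
    results: list[RunResult] = []
    best_spec, best_val = None, np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        optim = replace(base, **dict(zip(keys, combo)))
        run = train_convnet(
            dataset, images, conv_spec, optim, seed, dataset_id=dataset_id
        )
        results.append(run)
        if run.rmse_val < best_val:
            best_val = run.rmse_val
            best_spec = optim
    return best_spec, results
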