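"""Metrics, null baselines, ensembles, Y-scrambling, residual diagnostics.

Conventions: RMSE in pIC50 units; R² is by default the square of Pearson's r
between observed and predicted (the convention used when judging Y-scrambling
collapse), with the coefficient-of-determination variant also exported.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chem_data import BioactivityDataset


def rmse(observed, predicted) -> float:
    """Root mean squared error."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def pearson_r(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(obs, pred).statistic)


def r_squared(observed, predicted, kind: str = "pearson") -> float:
    """R²: squared Pearson correlation (default) or 1 - SSE/SST."""
    if kind == "pearson":
        return pearson_r(observed, predicted) ** 2
    if kind == "coefficient_of_determination":
        obs = np.asarray(observed, dtype=float)
        pred = np.asarray(predicted, dtype=float)
        sst = np.sum((obs - obs.mean()) ** 2)
        if sst == 0:
            raise ValueError("R^2 undefined for constant observed values")
        return float(1.0 - np.sum((obs - pred) ** 2) / sst)
    raise ValueError(f"unknown R^2 kind {kind!r}")


def mean_predictor_rmse(
    dataset: BioactivityDataset, target_id: str | None = None
) -> float:
    """Test RMSE of the constant model predicting the training-set mean pIC50.

    The null baseline any learned model must beat: with imbalanced ChEMBL-like
    label distributions this constant predictor already scores deceptively
    well, so learned models are always reported against it.
    """
    labels = dataset.labels(target_id)
    train = [labels[r.compound_id] for r in dataset.subset("train") if r.compound_id in labels]
    test = [labels[r.compound_id] for r in dataset.subset("test") if r.compound_id in labels]
    if not train or not test:
        raise ValueError("mean-predictor baseline needs non-empty train and test splits")
    mean = float(np.mean(train))
    return rmse(test, [mean] * len(test))


@dataclass
class EnsembleResult:
    """Averaged predictions of two models scored against shared observations."""

    component_rmses: tuple[float, float]
    ensemble_rmse: float
    relative_improvement_vs_each: tuple[float, float]


def ensemble_average(
    preds_a: dict[str, float], preds_b: dict[str, float], observed: dict[str, float]
) -> EnsembleResult:
    """Per-compound average of two prediction maps, scored against observed.

    The ensemble RMSE can never exceed the mean of the component RMSEs
    (convexity of the Euclidean norm).
    """
    ids = sorted(observed)
    missing = [i for i in ids if i not in preds_a or i not in preds_b]
    if missing:
        raise ValueError(f"predictions missing for: {', '.join(missing[:10])}")
    obs = np.array([observed[i] for i in ids])
    a = np.array([preds_a[i] for i in ids])
    b = np.array([preds_b[i] for i in ids])
    r_a, r_b = rmse(obs, a), rmse(obs, b)
    r_e = rmse(obs, (a + b) / 2.0)
    rel = tuple(
        100.0 * (r_e - r) / r if r > 0 else 0.0 for r in (r_a, r_b)
    )
    return EnsembleResult((r_a, r_b), r_e, rel)


def y_scramble(
    dataset: BioactivityDataset, seed: int, target_id: str | None = None
) -> BioactivityDataset:
    """Permute train+validation labels uniformly; test labels untouched.

    Structures and the split itself are unchanged — a model trained on the
    scrambled dataset can only learn chance correlation, so its test R² should
    collapse to ~0.
    """
    rng = np.random.default_rng(seed)
    tid = target_id if target_id is not None else dataset.target_ids[0]
    out = copy.deepcopy(dataset)
    pool_ids = [
        r.compound_id
        for r in out.records
        if out.split.get(r.compound_id) in ("train", "validation") and tid in r.activities
    ]
    values = [next(r for r in out.records if r.compound_id == cid).activities[tid] for cid in pool_ids]
    perm = rng.permutation(len(values))
    by_id = {r.compound_id: r for r in out.records}
    for cid, j in zip(pool_ids, perm):
        by_id[cid].activities[tid] = values[j]
    return out


@dataclass
class ResidualDiagnostics:
    mean: float
    sd: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    het_slope: float
    het_slope_se: float
    het_p_value: float
    heteroscedastic: bool


def residual_diagnostics(
    observed, predicted, alpha: float = 0.01, min_points: int = 20
) -> ResidualDiagnostics:
    """Residual summary: moments, normal Q-Q pairs, heteroscedasticity check.

    Heteroscedasticity is quantified as the slope of |residual| regressed on
    the predicted value; the flag is raised when its p-value falls below
    ``alpha``. Normal Q-Q pairs are returned for plotting elsewhere.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {obs.size}")
    resid = obs - pred
    sd = float(np.std(resid, ddof=1))
    order = np.sort(resid)
    n = resid.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    if np.std(pred) == 0 or sd == 0:
        slope, se, p = 0.0, 0.0, 1.0
    else:
        fit = stats.linregress(pred, np.abs(resid))
        slope, se, p = float(fit.slope), float(fit.stderr), float(fit.pvalue)
    return ResidualDiagnostics(
        mean=float(resid.mean()),
        sd=sd,
        qq_theoretical=theo,
        qq_sample=order,
        het_slope=slope,
        het_slope_se=se,
        het_p_value=p,
        heteroscedastic=bool(p < alpha),
    )
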