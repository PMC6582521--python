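"""Balanced fixed-effect full-factorial comparison of model runs.

Per-run performance (test RMSE in pIC50 units by default, configurable) is
modelled by ordinary least squares with treatment (dummy) coding:

    response ~ Dataset_i + Model_j + Batch_k + Augmentation_l + mu0 + eps

and, for the cross-family comparison, a two-factor model with the full
Dataset x Model interaction. Reference levels are absorbed into the
intercept, which on a balanced design equals the mean response of the
reference cell. Per-factor p-values come from a Type-II ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

FACTORS = ("dataset", "model", "batch", "augmentation")


@dataclass
class FactorialTable:
    """Rows of (dataset, model, batch, augmentation, replicate, response)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in (*FACTORS, "replicate", "response") if c not in self.frame.columns]
        if missing:
            raise ValueError(f"run table missing column(s): {', '.join(missing)}")


@dataclass
class FactorialModelFit:
    """Treatment-coded OLS fit of a factorial run table."""

    intercept: float
    coefficients: dict[tuple[str, str], float]
    adjusted_r2: float
    r2: float
    f_pvalue: float
    anova_pvalues: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    model: object = field(repr=False, default=None)


def _term(factor: str, reference: str) -> str:
    return f"C({factor}, Treatment(reference={reference!r}))"


def _parse_coefs(params: pd.Series) -> tuple[float, dict[tuple[str, str], float]]:
    intercept = float(params["Intercept"])
    coefs: dict[tuple[str, str], float] = {}
    for name, value in params.items():
        if name == "Intercept":
            continue
        # e.g. C(model, Treatment(reference='alexnet'))[T.vgg19bn]
        # interactions join two such pieces with ':'
        pieces = name.split(":")
        label_parts = []
        for piece in pieces:
            factor = piece.split("(")[1].split(",")[0]
            level = piece.split("[T.")[1].rstrip("]")
            label_parts.append((factor, level))
        if len(label_parts) == 1:
            coefs[label_parts[0]] = float(value)
        else:
            key = (
                ":".join(f for f, _ in label_parts),
                ":".join(l for _, l in label_parts),
            )
            coefs[key] = float(value)
    return intercept, coefs


def _fit(formula: str, df: pd.DataFrame, factors: list[str]) -> FactorialModelFit:
    try:
        res = smf.ols(formula, data=df).fit()
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"factorial fit failed: {exc}") from exc
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        cells = (
            df.groupby(factors, observed=True).size().reset_index().rename(columns={0: "n"})
        )
        raise ValueError(
            "rank-deficient design (inestimable effects); observed cells:\n"
            + cells.to_string(index=False)
        )
    intercept, coefs = _parse_coefs(res.params)
    anova = anova_lm(res, typ=2)
    pvals = {}
    for idx in anova.index:
        if idx == "Residual":
            continue
        pieces = idx.split(":")
        factors_in_term = [p.split("(")[1].split(",")[0] for p in pieces]
        pvals[":".join(factors_in_term)] = float(anova.loc[idx, "PR(>F)"])
    return FactorialModelFit(
        intercept=intercept,
        coefficients=coefs,
        adjusted_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        f_pvalue=float(res.f_pvalue),
        anova_pvalues=pvals,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        model=res,
    )


def _check_levels(df: pd.DataFrame, factors: list[str], references: dict[str, str]) -> None:
    for f in factors:
        levels = df[f].astype(str).unique()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels, found {list(levels)}")
        if references[f] not in levels:
            raise ValueError(
                f"reference level {references[f]!r} absent from factor {f!r}"
            )


def fit_main_effects(
    table: FactorialTable,
    references: dict[str, str] | None = None,
    response: str = "response",
) -> FactorialModelFit:
    """Main-effects OLS: response ~ dataset + model + batch + augmentation.

    ``references`` maps factor name -> reference level (defaults to the
    lexicographically first level of each factor).
    """
    df = table.frame.copy()
    for f in FACTORS:
        df[f] = df[f].astype(str)
    # default reference level: lexicographically first (row-order independent)
    refs = {f: sorted(df[f].unique())[0] for f in FACTORS}
    if references:
        refs.update({k: str(v) for k, v in references.items()})
    _check_levels(df, list(FACTORS), refs)
    formula = f"{response} ~ " + " + ".join(_term(f, refs[f]) for f in FACTORS)
    return _fit(formula, df, list(FACTORS))


def fit_interaction(
    table: FactorialTable,
    references: dict[str, str] | None = None,
    response: str = "response",
) -> FactorialModelFit:
    """Two-factor OLS with interaction: dataset + model + dataset:model."""
    df = table.frame.copy()
    for f in ("dataset", "model"):
        df[f] = df[f].astype(str)
    refs = {f: sorted(df[f].unique())[0] for f in ("dataset", "model")}
    if references:
        refs.update({k: str(v) for k, v in references.items()})
    _check_levels(df, ["dataset", "model"], refs)
    d, m = _term("dataset", refs["dataset"]), _term("model", refs["model"])
    formula = f"{response} ~ {d} + {m} + {d}:{m}"
    return _fit(formula, df, ["dataset", "model"])


def select_best_per_cell(runs, architecture_order: list[str] | None = None) -> list:
    """For each (dataset, replicate), keep the ConvNet run with lowest test RMSE.

    Ties break by position in ``architecture_order`` (default: order of first
    appearance in ``runs``).
    """
    if architecture_order is None:
        architecture_order = []
        for r in runs:
            if r.model_id not in architecture_order:
                architecture_order.append(r.model_id)
    rank = {m: i for i, m in enumerate(architecture_order)}
    best: dict[tuple, object] = {}
    for r in runs:
        key = (r.dataset_id, r.replicate)
        cur = best.get(key)
        if cur is None or (r.rmse_test, rank.get(r.model_id, len(rank))) < (
            cur.rmse_test,
            rank.get(cur.model_id, len(rank)),
        ):
            best[key] = r
    return [best[k] for k in sorted(best)]


def runs_to_table(runs) -> FactorialTable:
    """Build a factorial run table from RunResults (response = test RMSE)."""
    rows = [
        {
            "dataset": r.dataset_id,
            "model": r.model_id,
            "batch": r.batch_size,
            "augmentation": int(r.augmentation),
            "replicate": r.replicate,
            "response": r.rmse_test,
        }
        for r in runs
    ]
    return FactorialTable(pd.DataFrame(rows))


@dataclass
class BalanceReport:
    balanced: bool
    n_cells: int
    replicate_counts: pd.DataFrame
    offending_cells: pd.DataFrame


def check_balance(table: FactorialTable, factors=FACTORS) -> BalanceReport:
    """Count replicates per design cell and report whether counts are equal."""
    df = table.frame
    if df.empty:
        return BalanceReport(False, 0, pd.DataFrame(), pd.DataFrame())
    counts = df.groupby(list(factors), observed=True).size().rename("n").reset_index()
    modal = counts["n"].mode().iat[0]
    offending = counts[counts["n"] != modal]
    return BalanceReport(
        balanced=bool(offending.empty),
        n_cells=len(counts),
        replicate_counts=counts,
        offending_cells=offending,
    )
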