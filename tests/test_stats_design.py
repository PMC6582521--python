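"""Factorial linear-model fits: treatment coding, recovery of planted
effects, ANOVA, balance checking, best-run selection."""

import numpy as np
import pandas as pd
import pytest

from imgqsar import synthetic_data
from imgqsar.stats_design import (
    FactorialTable,
    check_balance,
    fit_interaction,
    fit_main_effects,
    runs_to_table,
    select_best_per_cell,
)

LEVELS = {
    "dataset": ["A", "B", "C", "D"],
    "model": ["m1", "m2", "m3", "m4"],
    "batch": ["4", "16", "32"],
    "augmentation": ["0", "1"],
}

EFFECTS = {
    ("dataset", "B"): 0.3,
    ("dataset", "C"): -0.2,
    ("dataset", "D"): 0.1,
    ("model", "m2"): 0.5,
    ("model", "m3"): -0.4,
    ("model", "m4"): 0.25,
    ("batch", "16"): 0.15,
    ("batch", "32"): -0.1,
    ("augmentation", "1"): -0.05,
}


REFS = {"dataset": "A", "model": "m1", "batch": "4", "augmentation": "0"}


def make_table(noise_sd=0.0, replicates=1, seed=0, interactions=None):
    return synthetic_data.generate_run_table(
        LEVELS, EFFECTS, noise_sd, replicates, seed, intercept=1.0,
        interactions=interactions,
    )


class TestMainEffects:
    def test_noiseless_recovery_exact(self):
        table, _ = make_table()
        fit = fit_main_effects(table, references=REFS)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        for key, value in EFFECTS.items():
            assert fit.coefficients[key] == pytest.approx(value, abs=1e-8), key
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-8)

    def test_intercept_is_reference_cell_mean(self):
        table, _ = make_table()
        fit = fit_main_effects(table, references=REFS)
        df = table.frame
        ref = df[
            (df.dataset == "A") & (df.model == "m1")
            & (df.batch == "4") & (df.augmentation == "0")
        ]
        assert fit.intercept == pytest.approx(ref.response.mean(), abs=1e-8)

    def test_balanced_estimates_equal_marginal_mean_differences(self):
        """Brute-force oracle: on a balanced design, each treatment-coded
        main effect equals the difference of factor-level marginal means."""
        table, _ = make_table(noise_sd=0.1, replicates=4, seed=2)
        fit = fit_main_effects(table, references=REFS)
        df = table.frame
        for factor in LEVELS:
            marginal = df.groupby(factor)["response"].mean()
            ref_level = LEVELS[factor][0]
            for level in LEVELS[factor][1:]:
                oracle = marginal[level] - marginal[ref_level]
                assert fit.coefficients[(factor, level)] == pytest.approx(
                    oracle, abs=1e-8
                )

    def test_residuals_sum_to_zero_and_adjusted_r2_bounded(self):
        table, _ = make_table(noise_sd=0.2, replicates=3, seed=5)
        fit = fit_main_effects(table)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-8)
        assert fit.adjusted_r2 <= fit.r2
        assert np.allclose(fit.fitted + fit.residuals, table.frame.response)

    def test_row_order_invariance(self):
        table, _ = make_table(noise_sd=0.1, replicates=2, seed=7)
        fit1 = fit_main_effects(table)
        shuffled = FactorialTable(
            table.frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        fit2 = fit_main_effects(shuffled)
        for key in fit1.coefficients:
            assert fit1.coefficients[key] == pytest.approx(fit2.coefficients[key])

    def test_custom_reference_levels(self):
        table, _ = make_table()
        fit = fit_main_effects(table, references={"model": "m2"})
        # with m2 as reference, m1's coefficient is -0.5
        assert fit.coefficients[("model", "m1")] == pytest.approx(-0.5, abs=1e-8)

    def test_single_level_factor_rejected(self):
        table, _ = make_table()
        df = table.frame[table.frame.augmentation == "0"]
        with pytest.raises(ValueError, match="augmentation"):
            fit_main_effects(FactorialTable(df.reset_index(drop=True)))

    def test_noisy_estimates_close_to_truth(self):
        """With modest noise and replication every coefficient lands within
        3 standard errors of its planted value (single-draw sanity check; the
        full coverage simulation lives in the acceptance suite)."""
        table, _ = make_table(noise_sd=0.1, replicates=10, seed=1000)
        fit = fit_main_effects(table, references=REFS)
        bse = fit.model.bse
        for name, p in fit.model.params.items():
            if name == "Intercept":
                continue
            level = name.split("[T.")[1].rstrip("]")
            factor = name.split("(")[1].split(",")[0]
            truth = EFFECTS.get((factor, level), 0.0)
            assert abs(p - truth) <= 3 * bse[name]


class TestInteraction:
    def test_planted_cell_offset_recovered(self):
        interactions = {("dataset:model", "B:m3"): 0.5}
        table, _ = make_table(interactions=interactions)
        fit = fit_interaction(table)
        assert fit.coefficients[("dataset:model", "B:m3")] == pytest.approx(
            0.5, abs=1e-8
        )

    def test_additive_table_has_zero_interactions(self):
        table, _ = make_table()
        fit = fit_interaction(table)
        for (term, _), value in fit.coefficients.items():
            if ":" in term:
                assert value == pytest.approx(0.0, abs=1e-8)

    def test_single_model_level_rejected(self):
        table, _ = make_table()
        df = table.frame[table.frame.model == "m1"].reset_index(drop=True)
        with pytest.raises(ValueError, match="model"):
            fit_interaction(FactorialTable(df))


class TestBalance:
    def test_balanced_full_grid(self):
        table, _ = make_table(replicates=10)
        report = check_balance(table)
        assert report.balanced
        assert report.n_cells == 4 * 4 * 3 * 2
        assert set(report.replicate_counts.n) == {10}

    def test_missing_run_flags_cell(self):
        table, _ = make_table(replicates=2)
        df = table.frame.drop(index=0).reset_index(drop=True)
        report = check_balance(FactorialTable(df))
        assert not report.balanced
        assert len(report.offending_cells) == 1

    def test_empty_table(self):
        empty = FactorialTable(
            pd.DataFrame(columns=["dataset", "model", "batch", "augmentation",
                                  "replicate", "response"])
        )
        report = check_balance(empty)
        assert not report.balanced
        assert report.n_cells == 0


class _StubRun:
    def __init__(self, dataset_id, model_id, replicate, rmse_test):
        self.dataset_id = dataset_id
        self.model_id = model_id
        self.replicate = replicate
        self.rmse_test = rmse_test
        self.batch_size = 16
        self.augmentation = False


class TestBestPerCell:
    def test_lowest_rmse_selected(self):
        runs = [
            _StubRun("d", "arch1", 0, 0.8),
            _StubRun("d", "arch2", 0, 0.7),
        ]
        assert select_best_per_cell(runs)[0].model_id == "arch2"

    def test_tie_broken_by_architecture_order(self):
        runs = [
            _StubRun("d", "arch1", 0, 0.7),
            _StubRun("d", "arch2", 0, 0.7),
        ]
        assert select_best_per_cell(runs)[0].model_id == "arch1"
        assert (
            select_best_per_cell(runs, architecture_order=["arch2", "arch1"])[0].model_id
            == "arch2"
        )

    def test_count_contract(self):
        runs = [
            _StubRun(f"d{i}", f"arch{a}", m, 0.5 + 0.01 * a)
            for i in range(8)
            for m in range(10)
            for a in range(8)
        ]
        selected = select_best_per_cell(runs)
        assert len(selected) == 80
        assert all(r.model_id == "arch0" for r in selected)

    def test_runs_to_table_schema(self):
        runs = [_StubRun("d", "m", 0, 0.5)]
        table = runs_to_table(runs)
        assert list(table.frame.columns) == [
            "dataset", "model", "batch", "augmentation", "replicate", "response",
        ]
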