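"""Shared fixtures: a hand-computable toy activity table and small synthetic
datasets with rendered images for the model-training tests."""

from __future__ import annotations

import numpy as np
import pytest

from imgqsar import chem_data, imaging, synthetic_data, training
from imgqsar.chem_data import RawActivityRow


def _row(cid, smiles, value, units="nM", relation="=", target="T1"):
    return RawActivityRow(cid, smiles, value, units, relation, target)


@pytest.fixture(scope="session")
def toy_rows() -> list[RawActivityRow]:
    """10 raw rows: mixed units/relations, one salt, one inorganic, one
    duplicated (compound, target) pair, one non-positive value."""
    return [
        _row("C1", "CC(=O)Oc1ccccc1C(=O)O", 1000.0),        # kept, pIC50 6.0
        _row("C2", "CCO.[Na+].[Cl-]", 100.0),               # salt; kept as CCO, 7.0
        _row("C3", "[Fe+2]", 10.0),                          # inorganic, rejected
        _row("C4", "c1ccccc1", 50.0, relation=">"),         # relation filter
        _row("C5", "Cc1ccccc1", 50.0, units="ug.mL-1"),     # unit filter
        _row("C6", "Oc1ccccc1", 10.0),                       # replicate 1: 8.0
        _row("C6", "Oc1ccccc1", 1000.0),                     # replicate 2: 6.0
        _row("C7", "c1ccncc1", -5.0),                        # non-positive value
        _row("C8", "CCN", 200.0),                            # kept, 9 - log10(200)
        _row("C9", "CC(C)O", 1.0),                           # kept, 9.0
    ]


@pytest.fixture(scope="session")
def toy_expected() -> dict[str, float]:
    """Hand-computed surviving pIC50 values for the toy table."""
    return {
        "C1": 6.0,
        "C2": 7.0,
        "C6": 7.0,  # mean of 8.0 and 6.0 on the log scale
        "C8": 9.0 - np.log10(200.0),
        "C9": 9.0,
    }


def make_split_dataset(n_compounds: int, seed: int, **config_kwargs):
    """Generate, curate, and split a synthetic dataset."""
    cfg = synthetic_data.SyntheticSARConfig(
        n_compounds=n_compounds, seed=seed, **config_kwargs
    )
    rows, truth = synthetic_data.generate_library(cfg)
    ds, _ = chem_data.curate(rows)
    return training.split_dataset(ds, seed), truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """30-compound noise-free-ish dataset for fast training-loop tests."""
    ds, _ = make_split_dataset(30, seed=42)
    return ds


@pytest.fixture(scope="session")
def tiny_images(tiny_dataset):
    return {
        r.compound_id: imaging.render_kekule(r) for r in tiny_dataset.records
    }


@pytest.fixture(scope="session")
def sar_dataset():
    """Default-scale synthetic SAR dataset (600 compounds) with split."""
    ds, truth = make_split_dataset(600, seed=0)
    return ds
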