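"""Synthetic ChEMBL-like structure-activity data with known ground truth.

Compounds are enumerated from a small set of drug-like scaffolds with two
substitution points and a fixed substituent vocabulary. The latent activity
model is additive: true pIC50 = base + scaffold offset + the contributions of
the two substituents, plus i.i.d. normal measurement noise per emitted row.
Because most substituent contributions are near zero, the resulting pIC50
distribution is imbalanced with its mode in the 4-5 band, as is typical of
IC50 sets curated from public databases.

The generator emits the same raw-table schema the curation module consumes —
IC50 in nM with unit "nM" and relation "=", optional counterion fragments and
replicate measurements — alongside a noiseless ground-truth table, so every
pipeline stage (curation, imaging, modelling) is testable offline with a
recoverable planted signal.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_data import RawActivityRow
from .stats_design import FactorialTable

#: Scaffold templates (two substitution sites) and additive scaffold offsets.
SCAFFOLDS: dict[str, float] = {
    "c1cc({R1})ccc1C(=O)Nc1ccc({R2})cc1": 0.0,     # benzanilide
    "c1cc({R1})ccc1S(=O)(=O)Nc1ccc({R2})cc1": 0.1,  # sulfonanilide
    "c1cc({R1})ccc1Cc1ccc({R2})cc1": 0.2,           # diphenylmethane
    "c1cc({R1})ccc1-c1nc2cc({R2})ccc2[nH]1": 0.3,   # 2-arylbenzimidazole
    "c1cc({R1})ccc1Oc1ccc({R2})cn1": -0.1,          # aryloxypyridine
    "C1CN(c2ccc({R1})cc2)CCN1c1ccc({R2})cc1": 0.15,  # arylpiperazine
}

#: Substituent vocabulary with additive pIC50 contributions. Most are ~0 so
#: the activity distribution stays concentrated near the base value.
SUBSTITUENTS: dict[str, float] = {
    "[H]": 0.0,
    "F": 0.0,
    "CC": 0.0,
    "C": 0.0,
    "OC": 0.1,
    "Cl": 0.1,
    "O": 0.2,
    "C#N": 0.2,
    "N(C)C": 0.9,
    "C(F)(F)F": 1.3,
    "S(C)(=O)=O": 1.7,
    "[N+](=O)[O-]": -0.3,
}

#: Alternative contribution map used to decorrelate an optional second task.
_TASK2_ALT = {
    "[H]": 0.0, "F": 0.3, "CC": 0.8, "C": 0.0, "OC": 0.5, "Cl": 0.0,
    "O": 0.9, "C#N": 0.1, "N(C)C": 0.0, "C(F)(F)F": 0.2,
    "S(C)(=O)=O": 0.1, "[N+](=O)[O-]": 0.6,
}

COUNTERIONS = ("Cl", "OS(=O)(=O)O", "OC(=O)C")


@dataclass
class SyntheticSARConfig:
    """Generator settings; defaults define the package's study conditions."""

    n_compounds: int = 600
    base_activity: float = 4.5
    noise_sd: float = 0.3
    replicate_prob: float = 0.1
    salt_prob: float = 0.1
    multitask: bool = False
    task_correlation: float = 0.5
    seed: int = 0
    scaffolds: dict[str, float] = field(default_factory=lambda: dict(SCAFFOLDS))
    substituents: dict[str, float] = field(default_factory=lambda: dict(SUBSTITUENTS))

    def __post_init__(self) -> None:
        for p in (self.replicate_prob, self.salt_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (emulates database precision)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def _true_pic50(config: SyntheticSARConfig, scaffold: str, r1: str, r2: str, task2: bool) -> float:
    if task2:
        rho = config.task_correlation
        contrib = {
            k: rho * v + (1 - rho) * _TASK2_ALT.get(k, 0.0)
            for k, v in config.substituents.items()
        }
    else:
        contrib = config.substituents
    return (
        config.base_activity
        + config.scaffolds[scaffold]
        + contrib[r1]
        + contrib[r2]
    )


def enumerate_space(config: SyntheticSARConfig) -> list[tuple[str, str, str]]:
    """All (scaffold, R1, R2) combinations of the configured vocabulary."""
    return list(
        itertools.product(config.scaffolds, config.substituents, config.substituents)
    )


def _assemble_smiles(scaffold: str, r1: str, r2: str) -> str:
    smiles = scaffold.replace("{R1}", r1).replace("{R2}", r2)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - vocabulary is validated by tests
        raise ValueError(f"invalid assembled SMILES: {smiles}")
    return Chem.MolToSmiles(mol)


def generate_library(
    config: SyntheticSARConfig,
) -> tuple[list[RawActivityRow], pd.DataFrame]:
    """Sample a compound library and emit raw activity rows plus ground truth.

    Returns
    -------
    rows : list of RawActivityRow
        Uncurated table (IC50 in nM, unit "nM", relation "="); replicate rows
        carry independent noise; salted rows have a counterion fragment
        appended to the SMILES.
    truth : DataFrame
        One row per compound with the noiseless pIC50 per task.
    """
    space = enumerate_space(config)
    if config.n_compounds > len(space):
        raise ValueError(
            f"n_compounds={config.n_compounds} exceeds enumerable space "
            f"({len(space)} combinations)"
        )
    rng = np.random.default_rng(config.seed)
    chosen = [space[i] for i in rng.choice(len(space), config.n_compounds, replace=False)]

    tasks = ["T1", "T2"] if config.multitask else ["T1"]
    rows: list[RawActivityRow] = []
    truth_rows = []
    for idx, (scaffold, r1, r2) in enumerate(chosen):
        cid = f"SYN{idx:06d}"
        smiles = _assemble_smiles(scaffold, r1, r2)
        emitted = smiles
        if rng.random() < config.salt_prob:
            ion = COUNTERIONS[rng.integers(len(COUNTERIONS))]
            emitted = f"{smiles}.{ion}"
        truth_entry = {"compound_id": cid, "canonical_smiles": smiles}
        for t_i, task in enumerate(tasks):
            true_p = _true_pic50(config, scaffold, r1, r2, task2=(t_i == 1))
            truth_entry[f"true_pIC50_{task}"] = true_p
            n_reps = 1 + int(rng.random() < config.replicate_prob)
            for _ in range(n_reps):
                noisy_p = true_p + rng.normal(0.0, config.noise_sd)
                ic50_nm = _round_sig(10 ** (9.0 - noisy_p))
                rows.append(
                    RawActivityRow(
                        compound_id=cid,
                        structure=emitted,
                        standard_value=ic50_nm,
                        standard_units="nM",
                        standard_relation="=",
                        target_id=task,
                    )
                )
        truth_rows.append(truth_entry)
    return rows, pd.DataFrame(truth_rows)


def generate_run_table(
    levels: dict[str, list],
    effects: dict[tuple[str, str], float],
    noise_sd: float,
    replicates: int,
    seed: int,
    intercept: float = 1.0,
    interactions: dict[tuple[str, str], float] | None = None,
) -> tuple[FactorialTable, dict]:
    """Balanced factorial response table with planted additive effects.

    ``levels`` maps factor -> level list (first level = reference, effect 0);
    ``effects`` maps (factor, level) -> additive offset;
    ``interactions`` maps ((factor_a_level, factor_b_level)) offsets keyed as
    ((factor_a, level_a), (factor_b, level_b)) pairs flattened to
    (f"{fa}:{fb}", f"{la}:{lb}").

    Returns the table and the ground-truth effect map (including intercept).
    """
    for f, lv in levels.items():
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    rng = np.random.default_rng(seed)
    factor_names = list(levels)
    rows = []
    for combo in itertools.product(*levels.values()):
        cell = dict(zip(factor_names, combo))
        mean = intercept + sum(
            effects.get((f, str(l)), 0.0) for f, l in cell.items()
        )
        if interactions:
            for (key, lev), off in interactions.items():
                fa, fb = key.split(":")
                la, lb = lev.split(":")
                if str(cell.get(fa)) == la and str(cell.get(fb)) == lb:
                    mean += off
        for m in range(replicates):
            rows.append(
                {
                    **{f: str(l) for f, l in cell.items()},
                    "replicate": m,
                    "response": mean + rng.normal(0.0, noise_sd),
                }
            )
    df = pd.DataFrame(rows)
    for f in ("dataset", "model", "batch", "augmentation"):
        if f not in df.columns:
            df[f] = "na"
    truth = {"intercept": intercept, "effects": dict(effects)}
    if interactions:
        truth["interactions"] = dict(interactions)
    return FactorialTable(df), truth


def write_library(
    rows: list[RawActivityRow],
    truth: pd.DataFrame,
    config: SyntheticSARConfig,
    out_dir: str | Path,
) -> Path:
    """Write the raw table, ground truth, and a config echo; returns the CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "smiles": r.structure,
                "standard_value": r.standard_value,
                "standard_units": r.standard_units,
                "standard_relation": r.standard_relation,
                "target_id": r.target_id,
            }
            for r in rows
        ]
    )
    csv_path = out_dir / "activities.csv"
    table.to_csv(csv_path, index=False)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    echo = {k: v for k, v in vars(config).items() if not isinstance(v, dict)}
    (out_dir / "config.json").write_text(json.dumps(echo, indent=2, sort_keys=True))
    return csv_path
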