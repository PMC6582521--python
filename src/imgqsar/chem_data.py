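"""Curation of ChEMBL-style bioactivity tables and circular fingerprints.

The curation contract mirrors standard medicinal-chemistry practice for IC50
data: keep only rows measured in nM with an exact ('=') activity relation,
strip counterions/solvents by retaining the largest fragment, reject molecules
containing non-organic elements, convert IC50 [nM] to pIC50 = -log10(IC50 [M]),
and average replicate pIC50 values per (compound, target) pair on the log
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

#: Conventional medicinal-chemistry whitelist of "organic" elements. Anything
#: outside this set (metals, noble gases, ...) marks a fragment as inorganic.
ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

#: Fingerprint lengths supported throughout the package.
FINGERPRINT_LENGTHS = (128, 256, 512, 1024, 2048)

REQUIRED_COLUMNS = (
    "compound_id",
    "smiles",
    "standard_value",
    "standard_units",
    "standard_relation",
    "target_id",
)


class SchemaError(ValueError):
    """An input table is missing a required column."""


class StructureParseError(ValueError):
    """A structure string could not be parsed into a molecule."""


@dataclass(frozen=True)
class RawActivityRow:
    """One uncurated activity measurement.

    ``structure`` may be a SMILES string or a V2000 molblock; ``standard_value``
    is the reported IC50 in the reported units (only "nM" survives curation).
    """

    compound_id: str
    structure: str
    standard_value: float | None
    standard_units: str
    standard_relation: str
    target_id: str


@dataclass
class CompoundRecord:
    """A standardized molecule with curated activities.

    ``activities`` maps target_id -> pIC50 (molar -log10 units). Fingerprints
    are cached per (radius, n_bits) so repeated model builds reuse them.
    """

    compound_id: str
    canonical_structure: str
    activities: dict[str, float] = field(default_factory=dict)
    _fp_cache: dict[tuple[int, int], np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )


@dataclass
class BioactivityDataset:
    """A curated compound set with an optional train/validation/test split."""

    records: list[CompoundRecord]
    target_ids: list[str]
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate compound_id in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split_label: str) -> list[CompoundRecord]:
        return [r for r in self.records if self.split.get(r.compound_id) == split_label]

    def labels(self, target_id: str | None = None) -> dict[str, float]:
        tid = target_id if target_id is not None else self.target_ids[0]
        return {
            r.compound_id: r.activities[tid] for r in self.records if tid in r.activities
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for tid, p in r.activities.items():
                rows.append(
                    {
                        "compound_id": r.compound_id,
                        "canonical_smiles": r.canonical_structure,
                        "target_id": tid,
                        "pIC50": p,
                        "split": self.split.get(r.compound_id, ""),
                    }
                )
        return pd.DataFrame(rows)


def _parse_structure(structure: str) -> Chem.Mol:
    """Parse SMILES or a V2000 molblock; raise StructureParseError on failure."""
    if not structure or not structure.strip():
        raise StructureParseError("empty structure")
    text = structure.strip()
    # Molblocks are multi-line and carry the V2000/V3000 tag.
    if "\n" in structure and ("V2000" in structure or "V3000" in structure):
        mol = Chem.MolFromMolBlock(structure, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureParseError(f"unparseable structure: {text[:60]!r}")
    return mol


def _is_organic(mol: Chem.Mol) -> bool:
    return all(a.GetSymbol() in ORGANIC_ELEMENTS for a in mol.GetAtoms())


def standardize_structure(structure: str) -> tuple[str | None, str | None]:
    """Standardize one structure to a canonical SMILES.

    Keeps the fragment with the most heavy atoms (dropping counterions and
    solvents) and rejects molecules whose surviving fragment contains elements
    outside :data:`ORGANIC_ELEMENTS`.

    Returns
    -------
    (canonical_smiles, None) on success, (None, reason) on rejection.

    Raises
    ------
    StructureParseError
        If the structure cannot be parsed at all.
    """
    mol = _parse_structure(structure)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if _is_organic(f)]
    if not organic:
        return None, "inorganic element"
    # Tie-break: most heavy atoms, then highest MW, then smallest canonical
    # SMILES, so fragment choice is deterministic.
    def key(f: Chem.Mol) -> tuple:
        return (
            -f.GetNumHeavyAtoms(),
            -Descriptors.MolWt(f),
            Chem.MolToSmiles(f),
        )

    best = sorted(organic, key=key)[0]
    try:
        Chem.Kekulize(Chem.Mol(best), clearAromaticFlags=False)
    except Chem.KekulizeException:
        return None, "kekulization failure"
    return Chem.MolToSmiles(best), None


def filter_activities(
    rows: Sequence[RawActivityRow],
) -> tuple[list[RawActivityRow], dict[str, int]]:
    """Keep rows with units == "nM" and relation == "=" (after trimming).

    Returns the kept rows and an audit dict counting drops per rule. A row
    failing both predicates is counted under the unit rule (checked first).
    """
    kept: list[RawActivityRow] = []
    audit = {"kept": 0, "dropped_units": 0, "dropped_relation": 0, "dropped_value": 0}
    for row in rows:
        if row.standard_value is None or not np.isfinite(row.standard_value) or row.standard_value <= 0:
            audit["dropped_value"] += 1
            continue
        if str(row.standard_units).strip() != "nM":
            audit["dropped_units"] += 1
            continue
        if str(row.standard_relation).strip() != "=":
            audit["dropped_relation"] += 1
            continue
        kept.append(row)
        audit["kept"] += 1
    return kept, audit


def to_pic50(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 [M]) = 9 - log10(IC50 [nM])."""
    if not np.isfinite(ic50_nM) or ic50_nM <= 0:
        raise ValueError(f"IC50 must be a positive finite value in nM, got {ic50_nM}")
    return 9.0 - float(np.log10(ic50_nM))


def aggregate_replicates(pic50_values: Iterable[float]) -> float:
    """Average replicate measurements on the log (pIC50) scale."""
    vals = list(pic50_values)
    if not vals:
        raise ValueError("no values to aggregate")
    return float(np.mean(vals))


def curate(
    rows: Sequence[RawActivityRow],
) -> tuple[BioactivityDataset, dict[str, int]]:
    """Full curation pipeline: filter, standardize, convert, aggregate.

    Returns the curated dataset and an audit log with per-rule drop counts
    (unit/relation filters, parse errors, inorganic rejections).
    """
    kept, audit = filter_activities(rows)
    audit.update({"dropped_parse": 0, "dropped_inorganic": 0, "dropped_kekulize": 0})

    # compound_id -> canonical structure; (compound_id, target) -> pIC50 list
    structures: dict[str, str] = {}
    values: dict[tuple[str, str], list[float]] = {}
    rejected_ids: set[str] = set()
    for row in kept:
        if row.compound_id in rejected_ids:
            continue
        if row.compound_id not in structures:
            try:
                smiles, reason = standardize_structure(row.structure)
            except StructureParseError:
                audit["dropped_parse"] += 1
                rejected_ids.add(row.compound_id)
                continue
            if smiles is None:
                key = "dropped_kekulize" if reason == "kekulization failure" else "dropped_inorganic"
                audit[key] += 1
                rejected_ids.add(row.compound_id)
                continue
            structures[row.compound_id] = smiles
        values.setdefault((row.compound_id, row.target_id), []).append(
            to_pic50(row.standard_value)
        )

    records: dict[str, CompoundRecord] = {}
    for (cid, tid), vals in values.items():
        rec = records.setdefault(cid, CompoundRecord(cid, structures[cid]))
        rec.activities[tid] = aggregate_replicates(vals)
    target_ids = sorted({tid for _, tid in values})
    audit["curated_compounds"] = len(records)
    dataset = BioactivityDataset(list(records.values()), target_ids)
    return dataset, audit


def morgan_fingerprint(
    record: CompoundRecord, radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    """Hashed circular (Morgan) fingerprint folded to ``n_bits``, cached."""
    if n_bits not in FINGERPRINT_LENGTHS:
        raise ValueError(f"n_bits must be one of {FINGERPRINT_LENGTHS}, got {n_bits}")
    key = (radius, n_bits)
    if key in record._fp_cache:
        return record._fp_cache[key]
    mol = Chem.MolFromSmiles(record.canonical_structure)
    if mol is None:
        raise StructureParseError(
            f"invalid canonical structure for {record.compound_id}"
        )
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        fp[bit] = 1
    record._fp_cache[key] = fp
    return fp


def fingerprint_matrix(
    records: Sequence[CompoundRecord], radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    """Stack fingerprints of ``records`` into an (n, n_bits) float array."""
    return np.stack(
        [morgan_fingerprint(r, radius, n_bits) for r in records]
    ).astype(np.float64)


# ---------------------------------------------------------------------------
# Table I/O


def read_activity_table(path: str | Path) -> list[RawActivityRow]:
    """Read a CSV/TSV activity table into raw rows.

    Requires columns compound_id, smiles (or molblock), standard_value,
    standard_units, standard_relation, target_id.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    structure_col = "smiles" if "smiles" in df.columns else "molblock"
    required = [c for c in REQUIRED_COLUMNS if c != "smiles"] + [structure_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")
    rows = []
    for rec in df.itertuples(index=False):
        d = rec._asdict()
        try:
            value = float(d["standard_value"]) if d["standard_value"] != "" else None
        except ValueError:
            value = None
        rows.append(
            RawActivityRow(
                compound_id=d["compound_id"],
                structure=d[structure_col],
                standard_value=value,
                standard_units=d["standard_units"],
                standard_relation=d["standard_relation"],
                target_id=d["target_id"],
            )
        )
    return rows


def read_sdf(path: str | Path) -> list[RawActivityRow]:
    """Read a V2000 SDF whose records carry activity fields as SD tags."""
    rows = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        try:
            value = float(props.get("standard_value", "nan"))
        except (TypeError, ValueError):
            value = None
        rows.append(
            RawActivityRow(
                compound_id=str(props.get("compound_id", f"SDF{i}")),
                structure=Chem.MolToMolBlock(mol, kekulize=False),
                standard_value=value if value is not None and np.isfinite(value) else None,
                standard_units=str(props.get("standard_units", "")),
                standard_relation=str(props.get("standard_relation", "")),
                target_id=str(props.get("target_id", "")),
            )
        )
    return rows


def write_curated(
    dataset: BioactivityDataset, audit: Mapping[str, int], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the curated CSV and the JSON audit log; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "curated.csv"
    dataset.to_frame().to_csv(csv_path, index=False)
    audit_path = out_dir / "curation_audit.json"
    audit_path.write_text(json.dumps(dict(audit), indent=2, sort_keys=True))
    return csv_path, audit_path


def load_curated(path: str | Path) -> BioactivityDataset:
    """Load a curated CSV written by :func:`write_curated`."""
    df = pd.read_csv(path)
    records: dict[str, CompoundRecord] = {}
    split: dict[str, str] = {}
    for rec in df.itertuples(index=False):
        r = records.setdefault(
            str(rec.compound_id), CompoundRecord(str(rec.compound_id), rec.canonical_smiles)
        )
        r.activities[str(rec.target_id)] = float(rec.pIC50)
        if getattr(rec, "split", "") and isinstance(rec.split, str):
            split[str(rec.compound_id)] = rec.split
    ds = BioactivityDataset(
        list(records.values()), sorted(df["target_id"].astype(str).unique())
    )
    ds.split = split
    return ds
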