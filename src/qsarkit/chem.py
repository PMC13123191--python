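"""Structure standardization and feature generation.

A raw SMILES table becomes a list of :class:`MoleculeRecord` via a fixed,
deterministic standardization sequence, and each record list becomes one
numeric :class:`FeatureMatrix` per descriptor/fingerprint scheme.  The
standardization order is fixed (parse -> largest organic fragment ->
neutralize -> tautomer-normalize -> stereo-assign -> canonicalize) so that
the same input text always yields the same canonical SMILES, and so that
re-standardizing a canonical SMILES is a fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "FeatureScheme",
    "FeatureMatrix",
    "SCHEME_REGISTRY",
    "standardize",
    "featurize",
    "load_dataset",
]


class SchemeError(ValueError):
    """Unknown or unavailable feature scheme."""


class SchemaError(ValueError):
    """Input table does not match the declared columns/types."""


class EmptyInputError(ValueError):
    """An operation received no usable rows."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized compound.

    ``status`` is ``"ok"`` iff ``smiles_canonical`` is present; records with
    any other status are excluded from modeling but kept for the audit log.
    """

    id: str
    smiles_raw: str
    smiles_canonical: str | None
    target: float | str | None
    status: str  # ok | unparseable | empty_after_strip

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.smiles_canonical is not None):
            raise ValueError("status=ok iff canonical SMILES present")


#: The 14 supported descriptor/fingerprint schemes.  ``kind`` controls the
#: provider; mordred/pubchem have no installed provider and raise on use.
SCHEME_REGISTRY: dict[str, dict] = {
    "ecfp2": {"kind": "morgan", "radius": 1, "features": False},
    "ecfp4": {"kind": "morgan", "radius": 2, "features": False},
    "ecfp6": {"kind": "morgan", "radius": 3, "features": False},
    "fcfp2": {"kind": "morgan", "radius": 1, "features": True},
    "fcfp4": {"kind": "morgan", "radius": 2, "features": True},
    "fcfp6": {"kind": "morgan", "radius": 3, "features": True},
    "maccs": {"kind": "maccs"},
    "rdk5": {"kind": "rdkit", "max_path": 5},
    "rdk6": {"kind": "rdkit", "max_path": 6},
    "rdk7": {"kind": "rdkit", "max_path": 7},
    "avalon": {"kind": "avalon"},
    "mordred": {"kind": "unavailable"},
    "pubchem": {"kind": "unavailable"},
    "rdkdes": {"kind": "rdkdes"},
}

HASHED_KINDS = {"morgan", "rdkit", "avalon"}


@dataclass(frozen=True)
class FeatureScheme:
    """A named featurization scheme with its bit width (hashed schemes only)."""

    name: str
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.name not in SCHEME_REGISTRY:
            raise SchemeError(
                f"unknown scheme {self.name!r}; known: {sorted(SCHEME_REGISTRY)}"
            )
        if self.n_bits <= 0:
            raise SchemeError("n_bits must be positive")

    @property
    def kind(self) -> str:
        return SCHEME_REGISTRY[self.name]["kind"]

    @property
    def radius(self) -> int | None:
        return SCHEME_REGISTRY[self.name].get("radius")

    @property
    def is_hashed(self) -> bool:
        return self.kind in HASHED_KINDS or self.kind == "maccs"


@dataclass
class FeatureMatrix:
    """Row-aligned numeric features for one scheme, with aligned targets."""

    scheme: str
    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("duplicated feature column names")
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature rows and targets misaligned")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        out.insert(0, "__target__", self.y)
        out.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path, scheme: str) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="id")
        y = df.pop("__target__")
        return cls(scheme=scheme, X=df, y=y)


# ---------------------------------------------------------------------------
# standardization

_LARGEST = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER = rdMolStandardize.TautomerEnumerator()


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def standardize(
    smiles_raw: str, *, id: str = "0", target: float | str | None = None
) -> MoleculeRecord:
    """Standardize one SMILES string; never raises on bad input.

    Sequence: parse, keep the largest organic fragment, neutralize charges,
    canonicalize the tautomer (RDKit's enumerator ruleset), assign
    stereochemistry, emit canonical SMILES.  Unparseable text gives
    ``status="unparseable"``; inputs whose organic part vanishes after salt
    stripping give ``status="empty_after_strip"``.
    """
    text = "" if smiles_raw is None else str(smiles_raw).strip()
    mol = Chem.MolFromSmiles(text) if text else None
    if mol is None:
        return MoleculeRecord(id, text, None, target, "unparseable")
    if mol.GetNumHeavyAtoms() == 0:
        return MoleculeRecord(id, text, None, target, "empty_after_strip")
    try:
        mol = _LARGEST.choose(mol)
        if mol is None or mol.GetNumHeavyAtoms() == 0 or not _has_carbon(mol):
            return MoleculeRecord(id, text, None, target, "empty_after_strip")
        mol = _UNCHARGER.uncharge(mol)
        mol = _TAUTOMER.Canonicalize(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        canonical = Chem.MolToSmiles(mol)
    except Exception:
        return MoleculeRecord(id, text, None, target, "unparseable")
    return MoleculeRecord(id, text, canonical, target, "ok")


# ---------------------------------------------------------------------------
# featurization

# Ipc grows super-exponentially with molecule size and overflows the float64
# range long before RDKit reports non-finite values; it is excluded from the
# rdkdes suite.
_RDKDES_EXCLUDE = {"Ipc"}


def _mol(record: MoleculeRecord) -> Chem.Mol:
    return Chem.MolFromSmiles(record.smiles_canonical)


def _hashed_rows(records, scheme: FeatureScheme) -> np.ndarray:
    kind = scheme.kind
    if kind == "morgan":
        opts = {}
        if SCHEME_REGISTRY[scheme.name]["features"]:
            opts["atomInvariantsGenerator"] = (
                rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            )
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=scheme.radius, fpSize=scheme.n_bits, **opts
        )
        return np.vstack([gen.GetFingerprintAsNumPy(_mol(r)) for r in records])
    if kind == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=SCHEME_REGISTRY[scheme.name]["max_path"], fpSize=scheme.n_bits
        )
        return np.vstack([gen.GetFingerprintAsNumPy(_mol(r)) for r in records])
    if kind == "avalon":
        from rdkit.Avalon import pyAvalonTools

        rows = []
        for r in records:
            fp = pyAvalonTools.GetAvalonFP(_mol(r), scheme.n_bits)
            rows.append(np.frombuffer(bytes(fp.ToBitString(), "ascii"), "u1") - ord("0"))
        return np.vstack(rows)
    raise SchemeError(f"not a hashed scheme: {scheme.name}")


def featurize(
    records: Sequence[MoleculeRecord], scheme: FeatureScheme | str
) -> FeatureMatrix:
    """Compute the feature matrix for one scheme over ok-status records.

    Deterministic and order-pure: the row for a molecule depends only on its
    canonical SMILES and the scheme.  Non-finite descriptor values are stored
    as missing (NaN) rather than silently replaced.
    """
    if isinstance(scheme, str):
        scheme = FeatureScheme(scheme)
    records = list(records)
    if not records:
        raise EmptyInputError("no records to featurize")
    bad = [r.id for r in records if r.status != "ok"]
    if bad:
        raise ValueError(f"records not standardized ok: {bad[:5]}")
    ids = [r.id for r in records]
    targets = pd.Series([r.target for r in records], index=ids, name="target")

    kind = scheme.kind
    if kind == "unavailable":
        raise SchemeError(
            f"scheme {scheme.name!r} requires a descriptor provider that is "
            "not installed"
        )
    if kind == "maccs":
        mat = np.vstack(
            [np.array(MACCSkeys.GenMACCSKeys(_mol(r)), dtype=np.uint8) for r in records]
        )
        cols = [f"maccs:{i}" for i in range(mat.shape[1])]
        X = pd.DataFrame(mat, index=ids, columns=cols, dtype=float)
    elif kind == "rdkdes":
        rows = []
        for r in records:
            d = Descriptors.CalcMolDescriptors(_mol(r))
            rows.append({k: v for k, v in d.items() if k not in _RDKDES_EXCLUDE})
        X = pd.DataFrame(rows, index=ids).astype(float)
        X = X.reindex(sorted(X.columns), axis=1)
        X = X.where(np.isfinite(X))  # non-finite -> missing
    else:
        mat = _hashed_rows(records, scheme)
        cols = [f"{scheme.name}:{i}" for i in range(mat.shape[1])]
        X = pd.DataFrame(mat, index=ids, columns=cols, dtype=float)
    return FeatureMatrix(scheme=scheme.name, X=X, y=targets)


# ---------------------------------------------------------------------------
# dataset ingestion

def load_dataset(
    path: str | Path,
    smiles_col: str,
    target_col: str,
    *,
    task: str = "regression",
    id_col: str | None = None,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Read a SMILES/activity CSV and standardize every row.

    Returns the record list (row order preserved, one record per input row)
    and a standardization log with one row per record (id, status, reason).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path} contains no rows")
    for col in (smiles_col, target_col):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not in {list(df.columns)}")
    if task == "regression":
        targets = pd.to_numeric(df[target_col], errors="coerce")
        if targets.isna().any() and df[target_col].notna().any():
            bad = df.loc[targets.isna() & df[target_col].notna(), target_col]
            if len(bad):
                raise SchemaError(
                    f"non-numeric target values in regression mode: {bad.head(3).tolist()}"
                )
    else:
        targets = df[target_col]

    ids = (
        df[id_col].astype(str).tolist()
        if id_col and id_col in df.columns
        else [str(i) for i in range(len(df))]
    )
    records = [
        standardize(s, id=i, target=t)
        for i, s, t in zip(ids, df[smiles_col], targets)
    ]
    reasons = {
        "ok": "",
        "unparseable": "SMILES failed to parse",
        "empty_after_strip": "no organic fragment after salt stripping",
    }
    log = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "status": [r.status for r in records],
            "reason": [reasons[r.status] for r in records],
        }
    )
    return records, log
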