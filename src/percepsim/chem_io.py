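"""Structure and table I/O: SMILES standardization, pair/vote tables, model files.

Standardization follows the common salt-stripping recipe used when
preparing drug-like molecules for similarity work: keep the largest
covalent fragment (the parent species, dropping counterions) and
neutralize any charges that can be neutralized without breaking
standard valence.  Permanent charges (e.g. quaternary ammonium) are
left untouched.  Stereochemistry is preserved because it matters for
the downstream 3D treatment.

Tabular data is plain CSV with an explicit header; model files are
JSON with a ``schema_version`` field.  See :data:`TABLE_SCHEMAS` for
the registered table dialects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .exceptions import (
    SchemaError,
    SmilesParseError,
    StandardizationError,
    TableValidationError,
)

__all__ = [
    "MoleculeRecord",
    "MoleculePair",
    "ExpertVotes",
    "PairFeatureTable",
    "TABLE_SCHEMAS",
    "standardize_molecule",
    "read_pair_table",
    "write_pair_table",
    "read_model",
    "write_model",
    "dedup_records",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule with its input provenance.

    ``structure`` is an RDKit mol of the standardized species; it may
    carry 3D conformers (coordinates in Angstrom) after embedding.
    """

    id: str
    smiles_input: str
    smiles_standardized: str
    structure: Chem.Mol = field(compare=False, repr=False)

    @property
    def num_heavy_atoms(self) -> int:
        return self.structure.GetNumHeavyAtoms()


@dataclass(frozen=True)
class MoleculePair:
    """An unordered pair of molecules; (a, b) and (b, a) are the same pair."""

    pair_id: str
    mol_a: MoleculeRecord
    mol_b: MoleculeRecord
    provenance: str = ""

    def __eq__(self, other) -> bool:
        if not isinstance(other, MoleculePair):
            return NotImplemented
        mine = {self.mol_a.smiles_standardized, self.mol_b.smiles_standardized}
        theirs = {other.mol_a.smiles_standardized, other.mol_b.smiles_standardized}
        return self.pair_id == other.pair_id and mine == theirs

    def __hash__(self) -> int:
        key = frozenset(
            (self.mol_a.smiles_standardized, self.mol_b.smiles_standardized)
        )
        return hash((self.pair_id, key))


@dataclass(frozen=True)
class ExpertVotes:
    """Vote counts of a survey panel on one molecular pair.

    ``pxp`` is the fraction of experts who judged the pair similar.
    """

    pair_id: str
    n_similar: int
    n_total: int

    def __post_init__(self):
        if self.n_total <= 0:
            raise TableValidationError(
                f"pair {self.pair_id!r}: n_total must be positive, got {self.n_total}"
            )
        if not 0 <= self.n_similar <= self.n_total:
            raise TableValidationError(
                f"pair {self.pair_id!r}: need 0 <= n_similar <= n_total, "
                f"got n_similar={self.n_similar}, n_total={self.n_total}"
            )

    @property
    def pxp(self) -> float:
        return self.n_similar / self.n_total


# Registered CSV dialects: name -> (required columns, optional columns).
TABLE_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "features": (("pair_id", "tXT", "tCS"), ("n_similar", "n_total", "subset")),
    "votes": (("pair_id", "n_similar", "n_total"), ("tXT", "tCS", "subset")),
    "pairs": (
        ("pair_id", "smiles_a", "smiles_b"),
        ("tXT", "tCS", "n_similar", "n_total", "subset"),
    ),
}

_NUMERIC_DOMAINS = {"tXT": (0.0, 1.0), "tCS": (0.0, 2.0)}


@dataclass
class PairFeatureTable:
    """Validated table of molecular pairs with similarity features and votes.

    Thin wrapper over a :class:`pandas.DataFrame` whose column domains
    have been checked (tXT in [0,1], tCS in [0,2], vote counts
    consistent, pair_id unique).  A ``pxp`` column is derived whenever
    vote counts are present.
    """

    df: pd.DataFrame
    dialect: str = "features"

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        _validate_table(self.df, self.dialect)
        if "n_similar" in self.df.columns and "pxp" not in self.df.columns:
            self.df["pxp"] = self.df["n_similar"] / self.df["n_total"]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.df["pair_id"])

    def votes(self) -> list[ExpertVotes]:
        if "n_similar" not in self.df.columns:
            raise TableValidationError("table has no vote columns")
        return [
            ExpertVotes(str(r.pair_id), int(r.n_similar), int(r.n_total))
            for r in self.df.itertuples()
        ]


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

_UNCHARGER = rdMolStandardize.Uncharger()


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Largest fragment by heavy-atom count; ties by MW, then canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]

    def key(frag: Chem.Mol):
        return (
            frag.GetNumHeavyAtoms(),
            Descriptors.MolWt(frag),
            Chem.MolToSmiles(frag),
        )

    return max(frags, key=key)


def standardize_molecule(smiles: str, mol_id: str | None = None) -> MoleculeRecord:
    """Standardize a SMILES string into a :class:`MoleculeRecord`.

    Counterions are removed by keeping the largest covalent fragment, and
    remaining charges are neutralized where a standard valence allows
    (carboxylates are protonated, protonated amines deprotonated;
    quaternary nitrogens keep their permanent charge).  The operation is
    deterministic and idempotent: re-standardizing the output is a no-op.

    Raises
    ------
    SmilesParseError
        If ``smiles`` cannot be parsed.
    StandardizationError
        If nothing remains after fragment selection.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    mol = _largest_fragment(mol)
    if mol.GetNumAtoms() == 0:
        raise StandardizationError(
            f"empty molecule after fragment removal: {smiles!r}"
        )
    Chem.SanitizeMol(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(
        id=mol_id if mol_id is not None else canonical,
        smiles_input=smiles,
        smiles_standardized=canonical,
        structure=mol,
    )


def dedup_records(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Drop records whose standardized canonical SMILES was already seen."""
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.smiles_standardized not in seen:
            seen.add(rec.smiles_standardized)
            out.append(rec)
    return out


# --------------------------------------------------------------------------
# tabular I/O
# --------------------------------------------------------------------------

def _resolve_dialect(columns: set[str], dialect: str) -> str:
    if dialect != "auto":
        if dialect not in TABLE_SCHEMAS:
            raise SchemaError(
                f"unknown table dialect {dialect!r}; "
                f"registered: {sorted(TABLE_SCHEMAS)}"
            )
        return dialect
    # prefer the most specific schema whose required columns are present
    for name in ("pairs", "votes", "features"):
        required, _ = TABLE_SCHEMAS[name]
        if set(required) <= columns:
            return name
    raise SchemaError(
        f"header {sorted(columns)} matches no registered schema; "
        f"registered: {sorted(TABLE_SCHEMAS)}"
    )


def _validate_table(df: pd.DataFrame, dialect: str) -> None:
    required, optional = TABLE_SCHEMAS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"dialect {dialect!r}: missing required columns {missing}"
        )
    bad_rows: list[int] = []
    messages: list[str] = []
    for col, (lo, hi) in _NUMERIC_DOMAINS.items():
        if col not in df.columns:
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(values < lo) | (values > hi) | values.isna()].tolist()
        if bad:
            bad_rows.extend(bad)
            messages.append(f"{col} outside [{lo}, {hi}] in rows {bad}")
        df[col] = values
    if "n_similar" in df.columns or "n_total" in df.columns:
        if not {"n_similar", "n_total"} <= set(df.columns):
            raise SchemaError("vote columns n_similar and n_total must both be present")
        ns = pd.to_numeric(df["n_similar"], errors="coerce")
        nt = pd.to_numeric(df["n_total"], errors="coerce")
        bad = df.index[(ns < 0) | (nt <= 0) | (ns > nt) | ns.isna() | nt.isna()].tolist()
        if bad:
            bad_rows.extend(bad)
            messages.append(f"inconsistent vote counts in rows {bad}")
    if df["pair_id"].duplicated().any():
        dups = df.index[df["pair_id"].duplicated(keep=False)].tolist()
        bad_rows.extend(dups)
        messages.append(f"duplicate pair_id in rows {dups}")
    if bad_rows:
        raise TableValidationError("; ".join(messages), rows=sorted(set(bad_rows)))


def read_pair_table(path: str | Path, dialect: str = "auto") -> PairFeatureTable:
    """Read and validate a CSV pair/vote table.

    ``dialect`` names a registered schema (``features``, ``votes``,
    ``pairs``) or ``auto`` to infer one from the header.  Rows violating
    a column domain raise :class:`TableValidationError` listing the
    offending row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    resolved = _resolve_dialect(set(df.columns), dialect)
    return PairFeatureTable(df=df, dialect=resolved)


def write_pair_table(table: PairFeatureTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# model file I/O (thin wrappers; serialization lives with the model type)
# --------------------------------------------------------------------------

def write_model(model, path: str | Path) -> None:
    """Serialize a perception model to a JSON file (schema_version 1)."""
    from .perception_model import PerceptionModel

    if not isinstance(model, PerceptionModel):
        raise TypeError("write_model expects a PerceptionModel")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(model.to_json())


def read_model(path: str | Path):
    """Load a perception model from a JSON file written by :func:`write_model`."""
    from .perception_model import PerceptionModel

    return PerceptionModel.from_json(Path(path).read_text())
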