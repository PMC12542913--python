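"""Molecule and dataset I/O.

Molecules are carried as RDKit ``Mol`` objects with perceived aromaticity and
stereochemistry; every other module consumes that graph view.  Datasets are
plain CSV tables (``id,smiles,gap_kcal_mol``); per-atom Mulliken spin
densities travel in a long-format sidecar CSV (``id,atom_index,spin``).

Atom indexing convention: 0-based, heavy atoms only, in parsed-input order.
Spin tables refer to this order, which matches how quantum-chemistry outputs
are usually post-processed (hydrogen contributions folded into, or dropped
from, the heavy-atom list before export).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem


class ParseError(ValueError):
    """A SMILES string could not be parsed into a valid molecule."""


class RadicalError(ParseError):
    """The molecule carries unpaired electrons.

    Open-shell species are rejected at parse time: the datasets this package
    targets are curated to closed-shell molecules, and fragment H-capping is
    only defined for them.
    """


class DatasetError(ValueError):
    """A dataset or spin table violates the file contract."""


@dataclass
class MoleculeRecord:
    """One dataset entry.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    smiles : str
        SMILES of the molecule; must parse to a closed-shell species.
    gap : float or None
        Adiabatic S0-T1 gap in kcal/mol, if known.
    atom_spins : tuple of float or None
        Unitless Mulliken spin densities per heavy atom, in parsed-atom
        order of ``smiles``.
    """

    id: str
    smiles: str
    gap: float | None = None
    atom_spins: tuple[float, ...] | None = field(default=None)

    def mol(self) -> Chem.Mol:
        return parse_molecule(self.smiles)


def parse_molecule(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule.

    Aromaticity and stereo are perceived by RDKit's sanitizer; atom order is
    deterministic for a given input string.  Radical species are rejected
    (datasets are curated to closed-shell molecules).

    Raises
    ------
    ParseError
        If the SMILES is empty or invalid.
    RadicalError
        If any atom carries unpaired electrons.
    """
    if not smiles:
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    if any(a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms()):
        raise RadicalError(f"radical species rejected: {smiles!r}")
    return mol


def canonical_smiles(mol_or_smiles: Chem.Mol | str) -> str:
    """Canonical SMILES of a molecule (or of a SMILES string, via re-parse).

    Two representations of the same molecule map to one string; the result
    is a fixed point under re-parse/re-canonicalize.
    """
    if isinstance(mol_or_smiles, str):
        mol = parse_molecule(mol_or_smiles)
    else:
        mol = mol_or_smiles
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    return parse_molecule(smiles).GetNumAtoms()


GAP_COLUMN = "gap_kcal_mol"
_DATASET_COLUMNS = ("id", "smiles", GAP_COLUMN)


def read_dataset(path: str | Path) -> list[MoleculeRecord]:
    """Read a dataset CSV with header ``id,smiles,gap_kcal_mol``.

    The gap column may be empty.  Duplicate ids are an error.
    """
    df = pd.read_csv(path, dtype={"id": str, "smiles": str},
                     float_precision="round_trip")
    missing = [c for c in ("id", "smiles") if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {missing}")
    if GAP_COLUMN not in df.columns:
        df[GAP_COLUMN] = np.nan
    dups = df["id"][df["id"].duplicated()].tolist()
    if dups:
        raise DatasetError(f"{path}: duplicate ids {sorted(set(dups))}")
    records = []
    for row in df.itertuples(index=False):
        gap = getattr(row, GAP_COLUMN)
        records.append(MoleculeRecord(
            id=row.id,
            smiles=row.smiles,
            gap=None if pd.isna(gap) else float(gap),
        ))
    return records


def write_dataset(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records to CSV; SMILES are emitted in canonical form."""
    rows = [
        {"id": r.id, "smiles": canonical_smiles(r.smiles),
         GAP_COLUMN: "" if r.gap is None else repr(float(r.gap))}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_DATASET_COLUMNS)).to_csv(path, index=False)


def read_spins(path: str | Path,
               records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Attach per-atom spins from a ``id,atom_index,spin`` CSV to records.

    Every spin row must reference a known id, and each referenced molecule
    must receive exactly one spin per heavy atom (indices 0..n-1).  Returns
    new records; molecules absent from the spin file keep ``atom_spins=None``.
    """
    df = pd.read_csv(path, dtype={"id": str},
                     float_precision="round_trip")
    for col in ("id", "atom_index", "spin"):
        if col not in df.columns:
            raise DatasetError(f"{path}: missing required column {col!r}")
    by_id = {r.id: r for r in records}
    unknown = sorted(set(df["id"]) - set(by_id))
    if unknown:
        raise DatasetError(f"{path}: spin rows reference unknown id(s) {unknown}")
    out = []
    spin_groups = {k: g for k, g in df.groupby("id")}
    for rec in records:
        g = spin_groups.get(rec.id)
        if g is None:
            out.append(rec)
            continue
        n_heavy = heavy_atom_count(rec.smiles)
        idx = g["atom_index"].to_numpy()
        if sorted(idx.tolist()) != list(range(n_heavy)):
            raise DatasetError(
                f"{path}: spin table for id {rec.id!r} has atom indices "
                f"{sorted(idx.tolist())}, expected 0..{n_heavy - 1}")
        spins = np.empty(n_heavy, dtype=float)
        spins[idx] = g["spin"].to_numpy(dtype=float)
        out.append(MoleculeRecord(rec.id, rec.smiles, rec.gap,
                                  tuple(float(s) for s in spins)))
    return out


def write_spins(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write the spin sidecar CSV for records that carry ``atom_spins``."""
    rows = []
    for r in records:
        if r.atom_spins is None:
            continue
        for i, s in enumerate(r.atom_spins):
            rows.append({"id": r.id, "atom_index": i, "spin": repr(float(s))})
    pd.DataFrame(rows, columns=["id", "atom_index", "spin"]).to_csv(
        path, index=False)
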