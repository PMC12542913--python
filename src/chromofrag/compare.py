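"""Fragment-level dataset statistics and comparison.

Datasets are compared by the identity of their fragments' canonical capped
SMILES.  By default only unsaturated fragments enter the statistics —
saturated fragments carry no low-lying excitation and are discarded before
diversity and localization analysis.  Counting is per-molecule presence
(0/1 per molecule and key), so two identical chlorides in one molecule add
one, not two, to that key's database count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from chromofrag.fragmenter import FragmentKey, fragment_smiles
from chromofrag.molgraph import MoleculeRecord, ParseError, canonical_smiles

logger = logging.getLogger(__name__)


@dataclass
class FragmentTable:
    """Occurrence counts of fragment keys in one dataset.

    ``entries`` maps canonical capped SMILES to the number of molecules
    containing at least one fragment with that key.
    """

    dataset_id: str
    entries: dict[str, int] = field(default_factory=dict)
    n_molecules: int = 0
    n_skipped: int = 0

    @property
    def keys(self) -> set[str]:
        return set(self.entries)


@dataclass
class OverlapMatrix:
    """Shared-fragment counts between datasets.

    Diagonal: unique-fragment count per dataset.  Off-diagonal: number of
    fragment keys present in both datasets.  Symmetric, and every
    off-diagonal entry is bounded by the smaller of its two diagonals.
    """

    dataset_ids: list[str]
    matrix: np.ndarray

    def shared_keys(self, tables: Sequence[FragmentTable],
                    i: int, j: int) -> set[str]:
        return tables[i].keys & tables[j].keys

    def to_dict(self) -> dict:
        return {"dataset_ids": self.dataset_ids,
                "matrix": self.matrix.tolist()}


@dataclass
class MoleculeClassification:
    """Single/multiple-fragment and shared/unique status of one molecule."""

    id: str
    n_fragments: int
    multiplicity: str  # "single" | "multiple"
    sharing: str       # "shared" | "unique"


def build_fragment_table(records: Iterable[MoleculeRecord],
                         dataset_id: str = "",
                         only_unsaturated: bool = True) -> FragmentTable:
    """Fragment every record and count keys by per-molecule presence.

    Unparseable records are logged and skipped; the skip count is kept on
    the returned table.
    """
    table = FragmentTable(dataset_id=dataset_id)
    for rec in records:
        try:
            frags = fragment_smiles(rec.smiles, rec.id,
                                    only_unsaturated=only_unsaturated)
        except ParseError as exc:
            logger.warning("skipping record %s: %s", rec.id, exc)
            table.n_skipped += 1
            continue
        table.n_molecules += 1
        for key in {k.capped_smiles for _, k in frags}:
            table.entries[key] = table.entries.get(key, 0) + 1
    if table.n_skipped:
        logger.warning("dataset %s: skipped %d unparseable record(s)",
                       dataset_id, table.n_skipped)
    return table


def overlap_matrix(tables: Sequence[FragmentTable]) -> OverlapMatrix:
    """Pairwise shared-unique-fragment counts across datasets."""
    if len(tables) < 2:
        raise ValueError("need at least two fragment tables")
    ids = [t.dataset_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate dataset ids in {ids}")
    n = len(tables)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        m[i, i] = len(tables[i].entries)
        for j in range(i + 1, n):
            shared = len(tables[i].keys & tables[j].keys)
            m[i, j] = m[j, i] = shared
    return OverlapMatrix(dataset_ids=ids, matrix=m)


def classify_molecules(records: Sequence[MoleculeRecord],
                       shared_keys: set[str],
                       only_unsaturated: bool = True,
                       ) -> tuple[list[MoleculeClassification], dict]:
    """2x2 breakdown: single/multiple fragments x unique/shared.

    A molecule is *shared* when at least one of its fragment keys lies in
    ``shared_keys``.  Molecules with zero (unsaturated) fragments go to a
    separate no-chromophore bucket, excluded from the 2x2 table.  The
    summary carries absolute counts (summing to the classified size) and
    percentages (1 decimal, summing to ~100%).
    """
    classifications: list[MoleculeClassification] = []
    no_chromophore: list[str] = []
    counts = {("single", "unique"): 0, ("single", "shared"): 0,
              ("multiple", "unique"): 0, ("multiple", "shared"): 0}
    for rec in records:
        frags = fragment_smiles(rec.smiles, rec.id,
                                only_unsaturated=only_unsaturated)
        if not frags:
            no_chromophore.append(rec.id)
            continue
        n_frag = len(frags)
        multiplicity = "single" if n_frag == 1 else "multiple"
        keys = {k.capped_smiles for _, k in frags}
        sharing = "shared" if keys & shared_keys else "unique"
        counts[(multiplicity, sharing)] += 1
        classifications.append(MoleculeClassification(
            rec.id, n_frag, multiplicity, sharing))
    total = len(classifications)
    summary = {
        "n_classified": total,
        "n_no_chromophore": len(no_chromophore),
        "no_chromophore_ids": no_chromophore,
        "counts": {f"{m}_{s}": c for (m, s), c in counts.items()},
        "percent": {
            f"{m}_{s}": round(100.0 * c / total, 1) if total else 0.0
            for (m, s), c in counts.items()},
    }
    summary["percent_shared"] = round(
        100.0 * (counts[("single", "shared")] + counts[("multiple", "shared")])
        / total, 1) if total else 0.0
    summary["percent_multiple"] = round(
        100.0 * (counts[("multiple", "unique")] + counts[("multiple", "shared")])
        / total, 1) if total else 0.0
    return classifications, summary


def find_shared_molecules(records_a: Iterable[MoleculeRecord],
                          records_b: Iterable[MoleculeRecord]) -> list[str]:
    """Molecules present in both datasets, by canonical SMILES identity."""
    smiles_a = {canonical_smiles(r.smiles) for r in records_a}
    smiles_b = {canonical_smiles(r.smiles) for r in records_b}
    return sorted(smiles_a & smiles_b)


def build_fragments_db(tables: Sequence[FragmentTable],
                       min_count: int = 2) -> list[FragmentKey]:
    """Fragment keys occurring at least ``min_count`` times in >=1 dataset.

    The threshold is applied per dataset, not to the pooled count.  Output
    is sorted canonically for determinism.  Raising ``min_count`` can only
    shrink the result.
    """
    if not tables:
        raise ValueError("need at least one fragment table")
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    selected: set[str] = set()
    for t in tables:
        selected.update(k for k, c in t.entries.items() if c >= min_count)
    from chromofrag.fragmenter import is_unsaturated
    return [FragmentKey(s, is_unsaturated(s)) for s in sorted(selected)]


def augment_datasets(molecule_records: Sequence[MoleculeRecord],
                     fragment_records: Sequence[MoleculeRecord],
                     ) -> list[MoleculeRecord]:
    """Merge a molecule dataset with a fragment dataset by canonical SMILES.

    On collision the fragment-dataset record wins (its gap was computed on
    the minimal representation).  All records must carry gap values; the
    output has no duplicate canonical SMILES.
    """
    for rec in list(molecule_records) + list(fragment_records):
        if rec.gap is None:
            raise ValueError(f"record {rec.id!r} is missing a gap value")
    merged: dict[str, MoleculeRecord] = {}
    for rec in molecule_records:
        merged[canonical_smiles(rec.smiles)] = rec
    for rec in fragment_records:
        merged[canonical_smiles(rec.smiles)] = rec  # fragment entry wins
    return list(merged.values())
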