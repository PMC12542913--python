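"""Exciton-localization labeling from atomic Mulliken spin densities.

At a triplet minimum the per-atom Mulliken spin densities sum to ~2.  Summed
over a fragment's atoms (candidate plus boundary shell) they say where the
exciton sits: the fragment with the highest total spin is the molecule's
*main fragment*.  The magnitude of that maximum classifies the localization
regime:

* ``> 2.0``          truncation artifact of the fragment spin sum,
* ``>= 1.7``         cleanly localized triplet,
* ``[0.7, 1.3]``     likely charge-transfer state (spin split across two
                     fragments),
* ``< 0.65``         main fragment misassigned — the T1 minimum was not on
                     any unsaturated fragment,
* otherwise          intermediate (the unnamed gaps between regimes).

The 1.7 localization threshold is an analysis convention, not a physical
constant, and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from chromofrag.fragmenter import Fragment, FragmentKey, cap_fragment


@dataclass(frozen=True)
class LocalizationThresholds:
    """Region boundaries on the main fragment's total spin (unitless)."""

    localized_min: float = 1.7
    artifact_min: float = 2.0
    ct_low: float = 0.7
    ct_high: float = 1.3
    misassigned_max: float = 0.65

    def __post_init__(self):
        if not (self.misassigned_max < self.ct_low < self.ct_high
                < self.localized_min < self.artifact_min):
            raise ValueError(f"thresholds out of order: {self}")


REGIONS = ("localized", "truncation_artifact", "charge_transfer",
           "misassigned", "intermediate")


@dataclass
class SpinReport:
    """Per-fragment spin totals and the resulting localization label."""

    id: str
    per_fragment: list[tuple[FragmentKey, float]]
    main_fragment: FragmentKey
    main_spin: float
    region: str


class NoChromophoreError(ValueError):
    """The molecule has no unsaturated fragment to localize the exciton on."""


def fragment_spin(frag: Fragment, atom_spins: Sequence[float]) -> float:
    """Total spin of a fragment: sum of atomic spins over its atoms.

    Boundary atoms are included — a fragment owns its boundary shell.
    Overlapping boundary atoms may be counted by several fragments; that is
    accepted because main-fragment selection is an argmax, not a partition.
    """
    missing = [i for i in frag.atoms if i >= len(atom_spins)]
    if missing:
        raise ValueError(
            f"missing spin entries for atom indices {sorted(missing)} "
            f"(fragment of {frag.parent_id!r})")
    return float(sum(atom_spins[i] for i in frag.atoms))


def classify_region(spin: float,
                    thresholds: LocalizationThresholds = LocalizationThresholds(),
                    ) -> str:
    """Localization regime of a main-fragment spin value.

    Total on the real line; precedence: artifact (strictly above 2), then
    localized (2.0 itself is localized), charge transfer, misassigned,
    intermediate.  "Strictly above" is applied with a 1e-9 absolute
    tolerance so that a fragment covering the whole molecule, whose spin
    sum is 2 up to float summation error, does not flip into the artifact
    regime.
    """
    t = thresholds
    if spin > t.artifact_min + 1e-9:
        return "truncation_artifact"
    if spin >= t.localized_min:
        return "localized"
    if t.ct_low <= spin <= t.ct_high:
        return "charge_transfer"
    if spin < t.misassigned_max:
        return "misassigned"
    return "intermediate"


def assign_main_fragment(mol: Chem.Mol,
                         fragments: Sequence[Fragment],
                         atom_spins: Sequence[float],
                         thresholds: LocalizationThresholds = LocalizationThresholds(),
                         ) -> SpinReport:
    """Label a molecule with its main fragment and localization regime.

    Only unsaturated fragments are candidates — the misassigned regime
    arises precisely when the spin sits outside all of them.  Ties on the
    maximum spin break toward the lexicographically smallest capped SMILES.
    """
    if len(atom_spins) != mol.GetNumAtoms():
        raise ValueError(
            f"got {len(atom_spins)} spins for a molecule with "
            f"{mol.GetNumAtoms()} heavy atoms")
    per_fragment: list[tuple[FragmentKey, float]] = []
    parent_id = fragments[0].parent_id if fragments else ""
    for frag in fragments:
        key = cap_fragment(mol, frag)
        if not key.unsaturated:
            continue
        per_fragment.append((key, fragment_spin(frag, atom_spins)))
    if not per_fragment:
        raise NoChromophoreError(
            f"molecule {parent_id!r} has no unsaturated fragment")
    main_key, main_spin = min(
        per_fragment, key=lambda ks: (-ks[1], ks[0].capped_smiles))
    return SpinReport(
        id=parent_id,
        per_fragment=per_fragment,
        main_fragment=main_key,
        main_spin=main_spin,
        region=classify_region(main_spin, thresholds),
    )


def spin_histogram(spins: Sequence[float], bin_width: float = 0.05) -> dict:
    """Absolute and cumulative frequency table of main-fragment spins.

    Bins cover the observed range on a grid aligned to multiples of
    ``bin_width``; the cumulative fraction is non-decreasing and ends at 1.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    values = np.asarray(list(spins), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one spin value")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    cumulative = np.cumsum(counts) / values.size
    return {
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "cumulative": cumulative.tolist(),
    }
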