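"""Synthetic datasets with the statistical structure the analysis assumes.

Molecules are assembled from a library of known chromophore fragments joined
by unbranched saturated alkyl linkers.  Linker carbons are never candidate
atoms, so fragmentation provably recovers the planted chromophore multiset —
every downstream module's test becomes a label-recovery test.

The gap oracle mirrors the adiabatic-gap definition (lowest free-energy
difference over the accessible triplet minima): each planted fragment has a
base gap, shifted by its molecular context, and the molecule's label is the
minimum of the shifted values plus observation noise.  Context shifts are
pairwise-additive: a fixed effect e(core, neighbor), drawn once per ordered
fragment pair from Normal(0, sigma_sub) when the library is set up, so the
shift on a fragment is Gaussian at scale sigma_sub per substituent yet
deterministic given the molecular structure — a learnable signal for the
delta model, exactly zero when sigma_sub is 0.

Triplet spin densities are planted per molecule in one of the localization
regimes (localized / charge-transfer / misassigned) with configurable
proportions, summing to ~2 over the heavy atoms.

Base gap values are free parameters of the oracle with no claim of physical
accuracy; the toluene and propene entries are set to the two allylbenzene
minima (85.7 and 62.4 kcal/mol) so the classic two-minimum story is
reproduced by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from chromofrag.fragmenter import find_candidate_atoms, fragment_smiles
from chromofrag.molgraph import MoleculeRecord, canonical_smiles, parse_molecule

#: Default chromophore library: (capped SMILES, base gap kcal/mol).  Every
#: entry carries at least one saturated methyl "handle" so linkers attach at
#: boundary atoms and the capped fragment identity survives assembly.
DEFAULT_LIBRARY: tuple[tuple[str, float], ...] = (
    ("Cc1ccccc1", 85.7),        # toluene (phenyl-localized minimum)
    ("C=CC", 62.4),             # propene (alkene-localized minimum)
    ("CC=CC", 66.0),
    ("C=C(C)C", 76.0),
    ("CC#CC", 75.0),
    ("CC=O", 78.0),
    ("CC(C)=O", 80.5),
    ("C=CC(C)=O", 55.0),
    ("CC#N", 95.0),
    ("CC(N)=O", 88.0),
    ("CC(=O)OC", 90.0),
    ("CN(C)C=O", 92.0),
    ("CS(C)=O", 98.0),
    ("Cc1ccco1", 72.0),
    ("Cc1cccs1", 68.5),
    ("Cc1ccsc1", 69.5),
    ("Cc1ccccn1", 82.0),
    ("Cc1ccc(C)cc1", 84.0),
    ("Cc1ccc(F)cc1", 86.5),
    ("CC(=O)c1ccccc1", 74.0),
    ("Cc1ccc2ccccc2c1", 60.8),
)


def default_library() -> list[tuple[str, float]]:
    return [(s, g) for s, g in DEFAULT_LIBRARY]


@dataclass
class OracleSpec:
    """Configuration of the synthetic data-generating process.

    Parameters
    ----------
    library
        (capped SMILES, base gap kcal/mol) chromophores; each must
        re-fragment to exactly itself and offer a saturated attachment
        handle.
    sigma_sub
        Scale (kcal/mol) of the per-substituent context effects.
    sigma_obs
        Observation noise (kcal/mol) on the gap labels.
    linker_range
        Inclusive range of alkyl linker lengths (atoms) between fragments.
    n
        Molecules per dataset.
    seed
        Seeds both the context-effect table and molecule assembly.
    k_weights
        Probabilities of a molecule containing 1..len(k_weights) fragments.
    """

    library: Sequence[tuple[str, float]] = field(
        default_factory=default_library)
    sigma_sub: float = 3.0
    sigma_obs: float = 0.5
    linker_range: tuple[int, int] = (1, 3)
    n: int = 1000
    seed: int = 0
    k_weights: tuple[float, ...] = (0.45, 0.30, 0.15, 0.10)

    def __post_init__(self):
        if self.sigma_sub < 0 or self.sigma_obs < 0:
            raise ValueError("noise scales must be non-negative")
        if not self.library:
            raise ValueError("fragment library is empty")
        if self.linker_range[0] < 1 or self.linker_range[1] < self.linker_range[0]:
            raise ValueError(f"bad linker range {self.linker_range}")
        seen = set()
        for smi, gap in self.library:
            if gap <= 0:
                raise ValueError(f"base gap for {smi!r} must be positive")
            canon = canonical_smiles(smi)
            if canon in seen:
                raise ValueError(f"duplicate library fragment {canon!r}")
            seen.add(canon)
            frags = fragment_smiles(smi)
            if len(frags) != 1 or frags[0][1].capped_smiles != canon:
                raise ValueError(
                    f"library fragment {smi!r} fails re-fragmentation "
                    "idempotence (must cap back to itself)")
            if not _handles(parse_molecule(smi)):
                raise ValueError(
                    f"library fragment {smi!r} has no saturated attachment "
                    "handle")

    def pair_effects(self) -> dict[tuple[str, str], float]:
        """Fixed context-effect table e(core, neighbor), Normal(0, sigma_sub)."""
        rng = np.random.default_rng(self.seed)
        keys = [canonical_smiles(s) for s, _ in self.library]
        effects = {}
        for a in keys:
            for b in keys:
                effects[(a, b)] = float(rng.normal(0.0, self.sigma_sub))
        return effects


def _handles(mol: Chem.Mol) -> list[tuple[int, int]]:
    """(atom index, free H count) of saturated carbon attachment points."""
    cand = find_candidate_atoms(mol)
    out = []
    for a in mol.GetAtoms():
        if (a.GetIdx() not in cand and a.GetSymbol() == "C"
                and a.GetTotalNumHs() >= 1):
            out.append((a.GetIdx(), a.GetTotalNumHs()))
    return out


def _assemble(parts: list[Chem.Mol], linker_lengths: list[int],
              rng: np.random.Generator) -> str:
    """Join fragment molecules into a chain through alkyl linkers."""
    combined = Chem.RWMol()
    offsets = []
    for part in parts:
        offsets.append(combined.GetNumAtoms())
        for a in part.GetAtoms():
            na = Chem.Atom(a.GetAtomicNum())
            na.SetFormalCharge(a.GetFormalCharge())
            na.SetIsAromatic(a.GetIsAromatic())
            na.SetNumExplicitHs(a.GetNumExplicitHs())
            combined.AddAtom(na)
        for b in part.GetBonds():
            combined.AddBond(b.GetBeginAtomIdx() + offsets[-1],
                             b.GetEndAtomIdx() + offsets[-1],
                             b.GetBondType())
    capacity: dict[int, int] = {}
    for part, off in zip(parts, offsets):
        for idx, nh in _handles(part):
            capacity[idx + off] = nh

    def pick_handle(part_idx: int) -> int:
        lo = offsets[part_idx]
        hi = offsets[part_idx + 1] if part_idx + 1 < len(offsets) \
            else len(parts[part_idx].GetAtoms()) + lo
        avail = [i for i in sorted(capacity) if lo <= i < hi and capacity[i] > 0]
        if not avail:
            raise ValueError("fragment ran out of attachment capacity")
        pick = avail[int(rng.integers(len(avail)))]
        capacity[pick] -= 1
        return pick

    for p, length in enumerate(linker_lengths):
        a = pick_handle(p)
        b = pick_handle(p + 1)
        prev = a
        for _ in range(length):
            c = combined.AddAtom(Chem.Atom(6))
            combined.AddBond(prev, c, Chem.BondType.SINGLE)
            prev = c
        combined.AddBond(prev, b, Chem.BondType.SINGLE)
    mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_molecules(spec: OracleSpec,
                       ) -> tuple[list[MoleculeRecord], dict]:
    """Generate molecules with gap labels and a ground-truth sidecar.

    Each molecule is 1..len(k_weights) library chromophores joined by
    saturated alkyl linkers.  The label is the minimum over planted
    fragments of (base gap + context shift) plus Normal(0, sigma_obs).
    Fragmentation of every generated molecule is asserted to recover
    exactly its planted chromophore multiset.

    Returns (records, truth) where ``truth`` maps molecule id to planted
    fragments, per-fragment effective values, the argmin (core) fragment
    with its atom indices in the record's parsed order, and the noiseless
    label.
    """
    rng = np.random.default_rng(spec.seed)
    effects = spec.pair_effects()
    lib = [(canonical_smiles(s), float(g)) for s, g in spec.library]
    parts_cache = {s: parse_molecule(s) for s, _ in lib}
    k_probs = np.asarray(spec.k_weights, dtype=float)
    k_probs = k_probs / k_probs.sum()

    records: list[MoleculeRecord] = []
    truth: dict[str, dict] = {}
    for m in range(spec.n):
        k = int(rng.choice(len(k_probs), p=k_probs)) + 1
        chosen = [lib[int(rng.integers(len(lib)))] for _ in range(k)]
        lengths = [int(rng.integers(spec.linker_range[0],
                                    spec.linker_range[1] + 1))
                   for _ in range(k - 1)]
        smiles = _assemble([parts_cache[s] for s, _ in chosen], lengths, rng)

        planted = sorted(s for s, _ in chosen)
        recovered = fragment_smiles(smiles, only_unsaturated=False)
        rec_keys = sorted(key.capped_smiles for _, key in recovered)
        if rec_keys != planted:
            raise AssertionError(
                f"fragmentation of {smiles!r} recovered {rec_keys}, "
                f"planted {planted}")

        keys = [s for s, _ in chosen]
        effective = []
        for i, (s_i, base_i) in enumerate(chosen):
            shift = sum(effects[(s_i, keys[j])]
                        for j in range(k) if j != i)
            effective.append(base_i + shift)
        core_pos = int(np.argmin(effective))
        core_key = keys[core_pos]
        core_atoms = next(
            sorted(frag.atoms) for frag, key in recovered
            if key.capped_smiles == core_key)
        label_noiseless = float(min(effective))
        label = label_noiseless + float(rng.normal(0.0, spec.sigma_obs)) \
            if spec.sigma_obs > 0 else label_noiseless

        mid = f"mol-{m:05d}"
        records.append(MoleculeRecord(id=mid, smiles=smiles, gap=label))
        truth[mid] = {
            "k": k,
            "fragments": keys,
            "effective": [float(e) for e in effective],
            "core": core_key,
            "core_atoms": core_atoms,
            "label_noiseless": label_noiseless,
        }
    return records, truth


REGIMES = ("localized", "charge_transfer", "misassigned")


def generate_spins(records: Sequence[MoleculeRecord], truth: dict,
                   purity: float = 0.8, spin_noise: float = 0.0,
                   seed: int = 0,
                   ) -> tuple[list[MoleculeRecord], dict[str, str]]:
    """Plant per-atom triplet spin densities in known localization regimes.

    A ``purity`` fraction of molecules place ~1.9 spin on the argmin (core)
    fragment (localized); the remainder split evenly between planted
    charge-transfer (two fragments at ~1.0 each) and misassigned (<0.65 on
    every unsaturated fragment, the rest on linker atoms).  Regimes that
    are structurally infeasible for a molecule (charge transfer needs two
    fragments; misassigned needs non-fragment atoms) fall back to
    localized.  ``spin_noise`` jitters the planted fragment totals with a
    Normal(0, spin_noise) draw clipped to the planted regime's band, so
    the recorded regime is always the regime actually realized; 0 gives
    exact placements.

    Returns (records with ``atom_spins``, planted regime per id).
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    rng = np.random.default_rng(seed)
    p_other = (1.0 - purity) / 2.0
    out: list[MoleculeRecord] = []
    regimes: dict[str, str] = {}
    for rec in records:
        mol = parse_molecule(rec.smiles)
        n = mol.GetNumAtoms()
        frags = fragment_smiles(rec.smiles, rec.id, only_unsaturated=True)
        frag_atoms = [sorted(f.atoms) for f, _ in frags]
        frag_keys = [key.capped_smiles for _, key in frags]
        in_frag = set().union(*[set(a) for a in frag_atoms]) if frags else set()
        outside = [i for i in range(n) if i not in in_frag]
        core_key = truth[rec.id]["core"]
        core_pos = frag_keys.index(core_key)

        regime = str(rng.choice(REGIMES, p=[purity, p_other, p_other]))
        if regime == "charge_transfer" and len(frags) < 2:
            regime = "localized"
        if regime == "misassigned" and not outside:
            regime = "localized"

        def jitter(x: float, lo: float, hi: float) -> float:
            if spin_noise <= 0:
                return x
            return float(np.clip(x + rng.normal(0.0, spin_noise), lo, hi))

        spins = np.zeros(n)

        def spread(atoms: Sequence[int], total: float) -> None:
            if atoms:
                spins[list(atoms)] += total / len(atoms)

        if regime == "localized":
            s_main = jitter(1.9, 1.72, 2.0)
            spread(frag_atoms[core_pos], s_main)
            rest = [i for i in range(n) if i not in set(frag_atoms[core_pos])]
            spread(rest if rest else frag_atoms[core_pos], 2.0 - s_main)
        elif regime == "charge_transfer":
            other = (core_pos + 1) % len(frags)
            spread(frag_atoms[core_pos], jitter(1.0, 0.72, 1.28))
            spread(frag_atoms[other], jitter(1.0, 0.72, 1.28))
        else:  # misassigned
            spread(frag_atoms[core_pos], jitter(0.4, 0.05, 0.63))
            spread(outside, 1.6)

        out.append(MoleculeRecord(rec.id, rec.smiles, rec.gap,
                                  tuple(float(s) for s in spins)))
        regimes[rec.id] = regime
    return out, regimes


def generate_paired_methods(records: Sequence[MoleculeRecord],
                            slope: float = 1.0, intercept: float = 0.0,
                            sigma: float = 0.0, seed: int = 0,
                            ) -> np.ndarray:
    """Second gap column emulating a different level of theory.

    gap_B = slope * gap_A + intercept + Normal(0, sigma).
    """
    rng = np.random.default_rng(seed)
    gaps = np.array([r.gap for r in records], dtype=float)
    if np.isnan(gaps).any():
        raise ValueError("all records must carry gap values")
    noise = rng.normal(0.0, sigma, len(gaps)) if sigma > 0 else 0.0
    return slope * gaps + intercept + noise
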