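"""Functional-group fragmentation of molecules.

A molecule is decomposed around its *candidate atoms*: heteroatoms from a
predefined list (default N, O, S, P, Se, F, Cl, Br) and carbons bearing a
double, triple, or aromatic bond.  Each connected component of candidate
atoms, grown outward until the first non-candidate neighbor (the *boundary
shell*), is one fragment.  Severed bonds are implicitly capped with hydrogen,
so every fragment maps to a small closed-shell molecule — its canonical
capped SMILES is the fragment's identity for counting, overlap, and lookup.

Chemistry notes:

* Aromatic systems are never severed: all aromatic atoms are candidates, so
  bonds broken by capping are always single bonds.
* A cis double bond inside a small ring (size <= 7) that loses its ring on
  capping is emitted with an explicit Z annotation — cyclopentene's fragment
  is (Z)-butene, not stereo-undefined butene.  Larger rings drop the
  annotation.
* Acyclic double-bond stereo survives capping when both stereo-defining
  neighbors stay inside the fragment; tetrahedral centers keep their tag
  only when their full neighbor set is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable

from rdkit import Chem

from chromofrag.molgraph import ParseError, parse_molecule

#: Heteroatoms that seed fragments.  Iodine is deliberately absent: it may
#: occur in the parent chemical space but only ever joins a fragment as a
#: boundary atom.
DEFAULT_HETEROATOMS: frozenset[str] = frozenset(
    {"N", "O", "S", "P", "Se", "F", "Cl", "Br"})

_UNSATURATED_BOND_TYPES = (
    Chem.BondType.DOUBLE, Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)

#: Largest ring size whose cis double bond is re-emitted as Z when the ring
#: is broken by capping (ring strain forces cis up to about cycloheptene).
RING_Z_MAX_SIZE = 7

_STEREO_DOUBLE = (
    Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS, Chem.BondStereo.STEREOTRANS)


class CappingError(ValueError):
    """Capping a fragment produced an un-parseable species."""


@dataclass(frozen=True)
class Fragment:
    """A candidate-atom connected component plus its boundary shell.

    Atom indices refer to the parent molecule's (parsed) atom order.
    """

    parent_id: str
    candidate_atoms: FrozenSet[int]
    boundary_atoms: FrozenSet[int]

    @property
    def atoms(self) -> frozenset[int]:
        return self.candidate_atoms | self.boundary_atoms

    def __post_init__(self):
        if not self.candidate_atoms:
            raise ValueError("fragment has no candidate atoms")
        if self.candidate_atoms & self.boundary_atoms:
            raise ValueError("candidate and boundary atom sets overlap")


@dataclass(frozen=True)
class FragmentKey:
    """Canonical H-capped identity of a fragment."""

    capped_smiles: str
    unsaturated: bool


def find_candidate_atoms(mol: Chem.Mol,
                         heteroatoms: Iterable[str] = DEFAULT_HETEROATOMS,
                         ) -> set[int]:
    """Indices of fragment-seeding atoms.

    Returns heteroatoms whose element is in ``heteroatoms``, plus every
    carbon incident to at least one double, triple, or aromatic bond.
    """
    hetero = frozenset(heteroatoms)
    out: set[int] = set()
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in hetero:
            out.add(atom.GetIdx())
        elif sym == "C" and any(
                b.GetBondType() in _UNSATURATED_BOND_TYPES
                for b in atom.GetBonds()):
            out.add(atom.GetIdx())
    return out


def fragment_molecule(mol: Chem.Mol,
                      parent_id: str = "",
                      heteroatoms: Iterable[str] = DEFAULT_HETEROATOMS,
                      ) -> list[Fragment]:
    """Decompose a molecule into fragments.

    One fragment per connected component of the candidate-atom-induced
    subgraph, each augmented with its first shell of non-candidate
    neighbors.  Fragments are unique as atom-index sets; two fragments with
    identical capped SMILES but different atoms (e.g. two alkyl chlorides
    on one ring) stay distinct.  A molecule with no candidate atoms yields
    an empty list.
    """
    cand = find_candidate_atoms(mol, heteroatoms)
    fragments: list[Fragment] = []
    seen: set[int] = set()
    for seed in sorted(cand):
        if seed in seen:
            continue
        comp = {seed}
        stack = [seed]
        while stack:
            i = stack.pop()
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in cand and j not in comp:
                    comp.add(j)
                    stack.append(j)
        seen |= comp
        boundary = {
            nb.GetIdx()
            for i in comp
            for nb in mol.GetAtomWithIdx(i).GetNeighbors()
            if nb.GetIdx() not in cand
        }
        fragments.append(Fragment(parent_id, frozenset(comp),
                                  frozenset(boundary)))
    return fragments


def cap_fragment(mol: Chem.Mol, frag: Fragment) -> FragmentKey:
    """H-cap a fragment and return its canonical identity.

    Builds the induced subgraph on ``frag.atoms``; severed bonds become
    implicit hydrogens on the retained atom (elements and formal charges
    preserved, never neutralized).  Stereo handling follows the module
    docstring.

    Raises
    ------
    CappingError
        If the capped species fails sanitization — never silently skipped.
    """
    n = mol.GetNumAtoms()
    atoms = sorted(frag.atoms)
    if not atoms or atoms[0] < 0 or atoms[-1] >= n:
        raise ValueError(f"fragment atoms {atoms} out of range for molecule "
                         f"with {n} atoms")
    old2new = {o: k for k, o in enumerate(atoms)}
    inset = frozenset(atoms)

    rw = Chem.RWMol()
    for o in atoms:
        a = mol.GetAtomWithIdx(o)
        na = Chem.Atom(a.GetAtomicNum())
        na.SetFormalCharge(a.GetFormalCharge())
        na.SetIsAromatic(a.GetIsAromatic())
        na.SetNumExplicitHs(a.GetNumExplicitHs())
        rw.AddAtom(na)

    ring_info = mol.GetRingInfo()
    kept: list[tuple[Chem.Bond, int]] = []
    # bonds added in parent order keeps neighbor ordering, and with it the
    # meaning of retained tetrahedral parity
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in old2new and j in old2new:
            bi = rw.AddBond(old2new[i], old2new[j], b.GetBondType()) - 1
            kept.append((b, bi))

    for b, bi in kept:
        nb = rw.GetBondWithIdx(bi)
        stereo = b.GetStereo()
        if stereo in _STEREO_DOUBLE:
            sa = list(b.GetStereoAtoms())
            if len(sa) == 2 and all(x in inset for x in sa):
                nb.SetStereoAtoms(old2new[sa[0]], old2new[sa[1]])
                nb.SetStereo(stereo)
        elif (b.GetBondType() == Chem.BondType.DOUBLE
              and b.IsInRing() and not b.GetIsAromatic()):
            _maybe_force_ring_cis(mol, ring_info, b, nb, inset, old2new)

    for o in atoms:
        a = mol.GetAtomWithIdx(o)
        tag = a.GetChiralTag()
        if tag != Chem.ChiralType.CHI_UNSPECIFIED and all(
                nb_.GetIdx() in inset for nb_ in a.GetNeighbors()):
            rw.GetAtomWithIdx(old2new[o]).SetChiralTag(tag)

    capped = rw.GetMol()
    try:
        Chem.SanitizeMol(capped)
    except Exception as exc:  # pragma: no cover - defensive
        raise CappingError(
            f"capping fragment {atoms} of {Chem.MolToSmiles(mol)} failed: "
            f"{exc}") from exc
    Chem.SetDoubleBondNeighborDirections(capped)
    smiles = Chem.MolToSmiles(capped)
    reparsed = Chem.MolFromSmiles(smiles)
    if reparsed is None:
        raise CappingError(f"capped SMILES {smiles!r} does not re-parse")
    return FragmentKey(capped_smiles=Chem.MolToSmiles(reparsed),
                       unsaturated=_has_unsaturation(reparsed))


def _maybe_force_ring_cis(mol, ring_info, bond, new_bond, inset, old2new):
    """Emit a ring double bond as Z when its (small) ring is broken.

    The ring geometry forces cis substituent arrangement for ring sizes up
    to RING_Z_MAX_SIZE; once the ring is opened by capping, that geometry
    is only expressible as an explicit Z annotation across the ring-path
    neighbors.
    """
    smallest = None
    for ring in ring_info.BondRings():
        if bond.GetIdx() in ring and len(ring) <= RING_Z_MAX_SIZE:
            if smallest is None or len(ring) < len(smallest):
                smallest = ring
    if smallest is None:
        return
    ring_atoms: set[int] = set()
    for rbi in smallest:
        rb = mol.GetBondWithIdx(rbi)
        ring_atoms.add(rb.GetBeginAtomIdx())
        ring_atoms.add(rb.GetEndAtomIdx())
    if ring_atoms <= inset:
        return  # ring survives capping intact; no annotation needed
    i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()

    def ring_path_neighbor(end: int) -> int | None:
        for nb in mol.GetAtomWithIdx(end).GetNeighbors():
            k = nb.GetIdx()
            if k not in (i, j) and k in ring_atoms and k in inset:
                return k
        return None

    ni, nj = ring_path_neighbor(i), ring_path_neighbor(j)
    if ni is not None and nj is not None:
        new_bond.SetStereoAtoms(old2new[ni], old2new[nj])
        new_bond.SetStereo(Chem.BondStereo.STEREOCIS)


def _has_unsaturation(mol: Chem.Mol) -> bool:
    return any(b.GetBondType() in _UNSATURATED_BOND_TYPES
               for b in mol.GetBonds())


def is_unsaturated(key: FragmentKey | str) -> bool:
    """True iff the capped molecule contains a double/triple/aromatic bond.

    Saturated fragments (alkyl halides, ethers, amines...) are not exciton
    candidates and are discarded before localization and overlap analysis.
    """
    if isinstance(key, FragmentKey):
        return key.unsaturated
    mol = parse_molecule(key)
    return _has_unsaturation(mol)


def fragment_smiles(smiles: str,
                    parent_id: str = "",
                    heteroatoms: Iterable[str] = DEFAULT_HETEROATOMS,
                    only_unsaturated: bool = False,
                    ) -> list[tuple[Fragment, FragmentKey]]:
    """Convenience: parse, fragment, and cap in one call."""
    mol = parse_molecule(smiles)
    out = []
    for frag in fragment_molecule(mol, parent_id, heteroatoms):
        key = cap_fragment(mol, frag)
        if only_unsaturated and not key.unsaturated:
            continue
        out.append((frag, key))
    return out
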