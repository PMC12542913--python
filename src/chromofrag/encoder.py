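"""Fixed-weight message-passing graph encoder.

Atom embeddings are produced by a seeded random-projection message-passing
network (an echo-state construction): initial atom features are projected
into a hidden space, then repeatedly updated from bond-typed neighbor
messages plus a skip connection back to the input features, with tanh
nonlinearities.  The weights are drawn once from a seeded generator and
never trained — all learning happens in the read-out heads that consume
pooled embeddings.

Each round also folds the mean-pooled global state back into every atom's
update (a master-node connection), so after a few rounds every atom's
embedding reflects both its K-hop neighborhood and whole-molecule identity.
This keeps encoding deterministic and fast while retaining the property the
delta-learning architecture needs: context-atom embeddings carry information
about the core even when it is many bonds away.

Masked encoding (``atom_subset``) restricts message passing to the induced
subgraph, with degrees recomputed inside the subgraph.  Because atom
features deliberately exclude ring membership and hydrogen counts, the
embedding of a fragment's atoms inside a molecule (masked to the fragment)
is identical to the embedding of the H-capped fragment parsed on its own —
the property that lets a head trained on isolated fragments transfer to
masked cores.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from rdkit import Chem

_ELEMENTS = ("C", "N", "O", "S", "P", "Se", "F", "Cl", "Br")
_MAX_DEGREE = 5
_BOND_CHANNELS = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
N_ATOM_FEATURES = len(_ELEMENTS) + 1 + 1 + (_MAX_DEGREE + 1) + 1
N_BOND_TYPES = 4


def atom_features(mol: Chem.Mol, atom_subset: Sequence[int] | None = None,
                  ) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Per-atom feature matrix and typed edge list of the (sub)graph.

    Features: element one-hot (with an "other" slot), aromatic flag, formal
    charge, in-subgraph degree one-hot, and a constant bias channel.
    Returned atom order follows ``atom_subset`` order (or full parsed
    order); edges are (row_i, row_j, bond_channel) with both directions
    implied by the caller.
    """
    if atom_subset is None:
        idx = list(range(mol.GetNumAtoms()))
    else:
        idx = sorted(atom_subset)
    pos = {o: k for k, o in enumerate(idx)}
    edges: list[tuple[int, int, int]] = []
    degree = np.zeros(len(idx), dtype=int)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in pos and j in pos:
            ch = _BOND_CHANNELS.get(b.GetBondType(), 0)
            edges.append((pos[i], pos[j], ch))
            degree[pos[i]] += 1
            degree[pos[j]] += 1
    feats = np.zeros((len(idx), N_ATOM_FEATURES))
    for k, o in enumerate(idx):
        a = mol.GetAtomWithIdx(o)
        sym = a.GetSymbol()
        col = _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS) - 1
        feats[k, col] = 1.0
        feats[k, len(_ELEMENTS)] = float(a.GetIsAromatic())
        feats[k, len(_ELEMENTS) + 1] = float(a.GetFormalCharge())
        feats[k, len(_ELEMENTS) + 2 + min(degree[k], _MAX_DEGREE)] = 1.0
        feats[k, -1] = 1.0
    return feats, edges


class GraphEncoder:
    """Seeded fixed-weight message-passing atom encoder.

    Parameters
    ----------
    dim : int
        Embedding width.
    n_steps : int
        Message-passing rounds; the receptive field is ``n_steps`` hops.
    seed : int
        Seeds the weight draw; two encoders with equal parameters produce
        bit-identical embeddings.
    """

    def __init__(self, dim: int = 96, n_steps: int = 6, seed: int = 0):
        self.dim = dim
        self.n_steps = n_steps
        self.seed = seed
        rng = np.random.default_rng(seed)
        s_in = 1.0 / np.sqrt(N_ATOM_FEATURES)
        s_h = 1.0 / np.sqrt(dim)
        self._w_in = rng.normal(0.0, s_in, (N_ATOM_FEATURES, dim))
        self._w_self = rng.normal(0.0, 0.7 * s_h, (dim, dim))
        self._w_nb = rng.normal(0.0, 0.7 * s_h, (dim, dim))
        self._w_skip = rng.normal(0.0, s_in, (N_ATOM_FEATURES, dim))
        self._w_glob = rng.normal(0.0, 0.5 * s_h, (dim, dim))
        # per-bond-type multiplicative gate on incoming messages
        self._gates = rng.uniform(0.5, 1.5, (N_BOND_TYPES, dim))

    def atom_embeddings(self, mol: Chem.Mol,
                        atom_subset: Sequence[int] | None = None) -> np.ndarray:
        """Embeddings for the atoms of ``mol`` (rows in sorted-subset order)."""
        feats, edges = atom_features(mol, atom_subset)
        h = np.tanh(feats @ self._w_in)
        skip = feats @ self._w_skip
        for _ in range(self.n_steps):
            msg = np.zeros_like(h)
            hn = h @ self._w_nb
            for i, j, ch in edges:
                g = self._gates[ch]
                msg[i] += g * hn[j]
                msg[j] += g * hn[i]
            glob = h.mean(axis=0) @ self._w_glob
            h = np.tanh(h @ self._w_self + msg + skip + glob)
        return h

    def pool(self, mol: Chem.Mol, atoms: Sequence[int],
             embeddings: np.ndarray | None = None,
             atom_subset: Sequence[int] | None = None) -> np.ndarray:
        """Sum-pool embeddings over ``atoms``; an empty set pools to zeros.

        ``embeddings`` rows follow sorted ``atom_subset`` order (full parsed
        order when no subset was used).
        """
        if embeddings is None:
            embeddings = self.atom_embeddings(mol, atom_subset)
        if atom_subset is None:
            rows = list(atoms)
        else:
            order = sorted(atom_subset)
            pos = {o: k for k, o in enumerate(order)}
            rows = [pos[a] for a in atoms]
        if not rows:
            return np.zeros(self.dim)
        return embeddings[rows].sum(axis=0)

    def encode_molecule(self, mol: Chem.Mol) -> np.ndarray:
        """Whole-molecule embedding (sum over all atoms, full graph)."""
        h = self.atom_embeddings(mol)
        return h.sum(axis=0)

    def encode_masked(self, mol: Chem.Mol, core_atoms: Sequence[int],
                      ) -> tuple[np.ndarray, np.ndarray]:
        """(core embedding, context atom embeddings) for a core mask.

        The core embedding is pooled over the core-induced subgraph (so it
        equals the embedding of the isolated capped fragment).  Context
        atoms keep their per-atom embeddings from full-graph message
        passing — one row per non-core atom, an empty (0, dim) array when
        the mask covers the whole molecule.
        """
        core = sorted(set(core_atoms))
        x_core = self.atom_embeddings(mol, core).sum(axis=0)
        rest = [i for i in range(mol.GetNumAtoms()) if i not in set(core)]
        if rest:
            ctx_rows = self.atom_embeddings(mol)[rest]
        else:
            ctx_rows = np.zeros((0, self.dim))
        return x_core, ctx_rows
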