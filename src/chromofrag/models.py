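"""Fragment-based prediction of adiabatic S0-T1 gaps.

Three schemes of increasing sophistication, all sharing the idea that the
gap of a multi-chromophore molecule is, to first order, the gap of the
fragment where the triplet localizes (the *core*):

* :class:`CoreLookupRegressor` — return the reference (e.g. DFT-computed)
  gap of the core fragment from a lookup table.
* :class:`CoreFragmentRegressor` — predict the core fragment's gap with a
  model trained on fragment data only.
* :class:`DeltaGapRegressor` — delta-learning: a core prediction plus a
  learned correction from the rest of the molecule, trained in two stages
  (fragments first, then molecules with per-molecule core masks).

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes); inputs are SMILES
strings plus, where needed, core atom masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_absolute_error, r2_score

from chromofrag.encoder import GraphEncoder
from chromofrag.molgraph import canonical_smiles, parse_molecule

# ---------------------------------------------------------------------------
# core masks


@dataclass(frozen=True)
class CoreMask:
    """Atom/bond subset of a molecule identified with its core fragment."""

    molecule_id: str
    atom_indices: frozenset[int]
    bond_indices: frozenset[int]

    def __post_init__(self):
        if not self.atom_indices:
            raise ValueError("core mask is empty")


class CoreMatchError(ValueError):
    """The core pattern does not match the molecule."""


def make_core_mask(mol: Chem.Mol, core_pattern: str,
                   molecule_id: str = "") -> CoreMask:
    """Mask the atoms and bonds matching a core SMILES/SMARTS pattern.

    The first match under RDKit's deterministic ordering is taken;
    symmetry-equivalent matches are interchangeable for prediction.  A
    warning reports multiple non-equivalent (distinct atom set) matches.
    """
    query = Chem.MolFromSmarts(core_pattern)
    matches: tuple = ()
    if query is not None:
        matches = mol.GetSubstructMatches(query, uniquify=True)
    if not matches:
        smi_query = Chem.MolFromSmiles(core_pattern)
        if smi_query is not None:
            matches = mol.GetSubstructMatches(smi_query, uniquify=True)
    if not matches:
        raise CoreMatchError(
            f"core pattern {core_pattern!r} does not match molecule "
            f"{Chem.MolToSmiles(mol)!r}")
    atom_sets = {frozenset(m) for m in matches}
    if len(atom_sets) > 1:
        warnings.warn(
            f"core pattern {core_pattern!r} has {len(atom_sets)} "
            "non-equivalent matches; taking the first", stacklevel=2)
    atoms = frozenset(matches[0])
    bonds = frozenset(
        b.GetIdx() for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms)
    return CoreMask(molecule_id, atoms, bonds)


# ---------------------------------------------------------------------------
# scheme 1: lookup


class LookupMiss(KeyError):
    """The core fragment key is absent from the lookup table."""


class CoreLookupRegressor(BaseEstimator, RegressorMixin):
    """Approximate a molecule's gap by its core fragment's tabulated value.

    ``fit`` ingests fragment SMILES and their reference gaps; ``predict``
    maps core-fragment SMILES to those values unchanged.  A miss raises
    :class:`LookupMiss` so callers can fall back to a model prediction.
    """

    def fit(self, X: Sequence[str], y: Sequence[float]):
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.table_ = {canonical_smiles(s): float(v) for s, v in zip(X, y)}
        self.n_features_in_ = 1
        return self

    def lookup(self, core_smiles: str) -> float:
        key = canonical_smiles(core_smiles)
        try:
            return self.table_[key]
        except KeyError:
            raise LookupMiss(key) from None

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return np.array([self.lookup(s) for s in X])


# ---------------------------------------------------------------------------
# trainable heads (NumPy, manual gradients)


def _relu(x):
    return np.maximum(x, 0.0)


class _Adam:
    def __init__(self, shapes: Mapping[str, tuple], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict, grads: Mapping[str, np.ndarray],
             b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)


def _init_heads(dim: int, hidden: int, rng: np.random.Generator) -> dict:
    s = np.sqrt(2.0 / dim)
    return {
        # core head: biased two-layer perceptron on the pooled core state
        "W1": rng.normal(0, s, (dim, hidden)), "b1": np.zeros(hidden),
        "w2": np.zeros(hidden), "b2": np.zeros(()),
        # context head: bias-free per-atom perceptron summed over context
        # atoms, so an empty context maps to exactly 0
        "V1": rng.normal(0, 0.5 * s, (dim, hidden)), "v2": np.zeros(hidden),
    }


def _forward(params, zc, ctx_rows, seg, use_ctx: bool):
    """Heads forward pass.

    ``zc``: (n, dim) pooled core states; ``ctx_rows``: (M, dim) context
    atom states across all samples; ``seg``: (M,) sample index per row.
    The correction of a sample is the sum of the bias-free per-atom
    outputs of its context rows (0 for samples with none).
    """
    n = len(zc)
    a1 = _relu(zc @ params["W1"] + params["b1"])
    core = a1 @ params["w2"] + params["b2"]
    if use_ctx and len(ctx_rows):
        c1 = _relu(ctx_rows @ params["V1"])
        atom_out = c1 @ params["v2"]
        corr = np.bincount(seg, weights=atom_out, minlength=n)
    else:
        c1 = None
        corr = np.zeros(n)
    return core, corr, a1, c1


def _train_heads(params: dict, zc: np.ndarray, ctx_rows: np.ndarray,
                 seg: np.ndarray, t: np.ndarray,
                 train_idx: np.ndarray, val_idx: np.ndarray,
                 *, use_ctx: bool, lr_core: float, lr_ctx: float,
                 epochs: int, sd_y: float) -> tuple[dict, list[float]]:
    """Full-batch Adam on MAE loss; returns best-validation params + log."""
    core_keys = ("W1", "b1", "w2", "b2")
    ctx_keys = ("V1", "v2") if use_ctx else ()
    opt_core = _Adam({k: params[k].shape for k in core_keys}, lr_core)
    opt_ctx = _Adam({k: params[k].shape for k in ctx_keys}, lr_ctx)
    n = len(zc)
    weight = np.zeros(n)
    weight[train_idx] = 1.0 / len(train_idx)
    best = {k: v.copy() for k, v in params.items()}
    best_mae = np.inf
    history: list[float] = []
    for _ in range(epochs):
        core, corr, a1, c1 = _forward(params, zc, ctx_rows, seg, use_ctx)
        resid = core + corr - t
        val_mae = float(np.mean(np.abs(resid[val_idx]))) * sd_y
        history.append(val_mae)
        if val_mae < best_mae:
            best_mae = val_mae
            best = {k: v.copy() for k, v in params.items()}
        dpred = np.sign(resid) * weight  # zero outside the training rows
        da1 = np.outer(dpred, params["w2"])
        da1[a1 <= 0] = 0.0
        opt_core.step(params, {
            "w2": a1.T @ dpred,
            "b2": np.asarray(dpred.sum()),
            "W1": zc.T @ da1,
            "b1": da1.sum(axis=0),
        })
        if use_ctx and len(ctx_rows):
            datom = dpred[seg]
            dc1 = np.outer(datom, params["v2"])
            dc1[c1 <= 0] = 0.0
            opt_ctx.step(params, {
                "v2": c1.T @ datom,
                "V1": ctx_rows.T @ dc1,
            })
    return best, history


# ---------------------------------------------------------------------------
# scheme 2: core-fragment model


class CoreFragmentRegressor(BaseEstimator, RegressorMixin):
    """Predict a fragment's gap from its molecular graph.

    Trained on fragment data only (the analogue of a fragment-database
    model); applied to a molecule by feeding it the molecule's core
    fragment.  The graph is embedded by a seeded fixed-weight
    message-passing encoder and read out by a small trained perceptron.
    """

    def __init__(self, dim: int = 96, n_steps: int = 6, hidden: int = 64,
                 lr: float = 0.02, epochs: int = 600,
                 val_fraction: float = 0.15, seed: int = 0):
        self.dim = dim
        self.n_steps = n_steps
        self.hidden = hidden
        self.lr = lr
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.seed = seed

    def _encoder(self) -> GraphEncoder:
        return GraphEncoder(dim=self.dim, n_steps=self.n_steps,
                            seed=self.seed)

    def fit(self, X: Sequence[str], y: Sequence[float]):
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("need equal-length, non-empty X and y")
        rng = np.random.default_rng(self.seed)
        enc = self._encoder()
        xc = np.stack([enc.encode_molecule(parse_molecule(s)) for s in X])
        y = np.asarray(y, dtype=float)
        self.x_mean_ = xc.mean(axis=0)
        self.x_scale_ = 1.0 / (xc.std(axis=0) + 1e-6)
        self.y_mean_ = float(y.mean())
        self.y_scale_ = float(y.std() + 1e-9)
        zc = (xc - self.x_mean_) * self.x_scale_
        t = (y - self.y_mean_) / self.y_scale_
        n = len(y)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if n > 4 else n
        val_idx = perm[:n_val]
        train_idx = perm[n_val:] if n > 4 else perm
        params = _init_heads(self.dim, self.hidden, rng)
        no_ctx = np.zeros((0, self.dim))
        no_seg = np.zeros(0, dtype=int)
        self.params_, self.history_ = _train_heads(
            params, zc, no_ctx, no_seg, t, train_idx, val_idx,
            use_ctx=False, lr_core=self.lr, lr_ctx=0.0, epochs=self.epochs,
            sd_y=self.y_scale_)
        self.n_features_in_ = self.dim
        return self

    def predict(self, X: Sequence[str]) -> np.ndarray:
        enc = self._encoder()
        xc = np.stack([enc.encode_molecule(parse_molecule(s)) for s in X])
        zc = (xc - self.x_mean_) * self.x_scale_
        core, _, _, _ = _forward(self.params_, zc, np.zeros((0, self.dim)),
                                 np.zeros(0, dtype=int), False)
        return self.y_mean_ + self.y_scale_ * core


# ---------------------------------------------------------------------------
# scheme 3: delta learning


@dataclass(frozen=True)
class DeltaPrediction:
    """Decomposed gap prediction (kcal/mol): total = core + correction."""

    core_value: float
    correction: float

    @property
    def total(self) -> float:
        return self.core_value + self.correction


class DeltaGapRegressor(BaseEstimator, RegressorMixin):
    """Delta-learning gap model: core prediction plus context correction.

    Message passing runs over the whole molecule; two global states are
    pooled from the atom embeddings — one over the core mask's atoms
    (computed on the core-induced subgraph, so it coincides with the
    embedding of the isolated capped fragment) and one over the remaining
    atoms.  Each feeds its own head: a biased perceptron for the core gap
    and a bias-free perceptron for the correction, which therefore returns
    exactly zero when the mask covers the whole molecule (empty context
    pools to the zero vector, and the context pathway has no additive
    terms).

    Training is two-stage: stage 1 fits the core pathway on fragment
    records alone (core mask = whole molecule, correction inactive);
    stage 2 fine-tunes end-to-end on the combined molecule+fragment set
    with per-molecule core masks, the core pathway at a reduced learning
    rate.  Validation MAE is logged per epoch and the best-validation
    weights are retained.  All randomness is seeded.
    """

    def __init__(self, dim: int = 96, n_steps: int = 6, hidden: int = 64,
                 lr: float = 0.02, stage1_epochs: int = 600,
                 stage2_epochs: int = 600, stage2_lr_factor: float = 0.3,
                 val_fraction: float = 0.15, seed: int = 0):
        self.dim = dim
        self.n_steps = n_steps
        self.hidden = hidden
        self.lr = lr
        self.stage1_epochs = stage1_epochs
        self.stage2_epochs = stage2_epochs
        self.stage2_lr_factor = stage2_lr_factor
        self.val_fraction = val_fraction
        self.seed = seed

    def _encoder(self) -> GraphEncoder:
        return GraphEncoder(dim=self.dim, n_steps=self.n_steps,
                            seed=self.seed)

    def fit(self, X: Sequence[str], y: Sequence[float], *,
            core_atoms: Sequence[Sequence[int]],
            fragments: Sequence[str], fragment_gaps: Sequence[float]):
        """Fit on molecules (with core masks) and fragment records.

        Parameters
        ----------
        X, y
            Molecule SMILES and gap labels (kcal/mol).
        core_atoms
            Per-molecule core atom indices (parsed-atom order of ``X``).
        fragments, fragment_gaps
            The fragment dataset for stage 1 (and stage-2 augmentation).
        """
        if len(X) != len(y) or len(X) != len(core_atoms):
            raise ValueError("X, y and core_atoms length mismatch")
        if len(fragments) == 0:
            raise ValueError("stage 1 needs a non-empty fragment set")
        missing = [i for i, c in enumerate(core_atoms) if not len(c)]
        if missing:
            raise ValueError(f"molecules at positions {missing[:5]} lack a "
                             "core annotation")
        rng = np.random.default_rng(self.seed)
        enc = self._encoder()

        xc_f = np.stack([enc.encode_molecule(parse_molecule(s))
                         for s in fragments])
        nf = len(fragments)
        xc_m, ctx_list, seg_list = [], [], []
        for pos, (s, core) in enumerate(zip(X, core_atoms)):
            mol = parse_molecule(s)
            c, rows = enc.encode_masked(mol, core)
            xc_m.append(c)
            if len(rows):
                ctx_list.append(rows)
                seg_list.append(np.full(len(rows), nf + pos, dtype=int))
        xc_all = np.vstack([xc_f, np.stack(xc_m)])
        ctx_rows = np.vstack(ctx_list) if ctx_list \
            else np.zeros((0, self.dim))
        seg = np.concatenate(seg_list) if seg_list \
            else np.zeros(0, dtype=int)
        y_all = np.concatenate([np.asarray(fragment_gaps, dtype=float),
                                np.asarray(y, dtype=float)])

        self.x_mean_ = xc_all.mean(axis=0)
        self.x_scale_ = 1.0 / (xc_all.std(axis=0) + 1e-6)
        # context scaling is multiplicative only, preserving zero exactly
        if len(ctx_rows):
            self.ctx_scale_ = 1.0 / (
                np.sqrt((ctx_rows ** 2).mean(axis=0)) + 1e-6)
        else:
            self.ctx_scale_ = np.ones(self.dim)
        self.y_mean_ = float(y_all.mean())
        self.y_scale_ = float(y_all.std() + 1e-9)

        zc_all = (xc_all - self.x_mean_) * self.x_scale_
        zrows = ctx_rows * self.ctx_scale_
        t_all = (y_all - self.y_mean_) / self.y_scale_

        params = _init_heads(self.dim, self.hidden, rng)

        # stage 1: core pathway on fragments alone
        perm = rng.permutation(nf)
        n_val = max(1, int(round(self.val_fraction * nf))) if nf > 4 else nf
        val1 = perm[:n_val]
        train1 = perm[n_val:] if nf > 4 else perm
        params, hist1 = _train_heads(
            params, zc_all[:nf], np.zeros((0, self.dim)),
            np.zeros(0, dtype=int), t_all[:nf], train1, val1,
            use_ctx=False, lr_core=self.lr, lr_ctx=0.0,
            epochs=self.stage1_epochs, sd_y=self.y_scale_)

        # stage 2: end-to-end on molecules + fragments, core lr reduced
        n_all = len(y_all)
        perm2 = rng.permutation(n_all)
        n_val2 = max(1, int(round(self.val_fraction * n_all)))
        val2 = perm2[:n_val2]
        train2 = perm2[n_val2:]
        params, hist2 = _train_heads(
            params, zc_all, zrows, seg, t_all, train2, val2, use_ctx=True,
            lr_core=self.lr * self.stage2_lr_factor, lr_ctx=self.lr,
            epochs=self.stage2_epochs, sd_y=self.y_scale_)

        self.params_ = params
        self.history_ = {"stage1_val_mae": hist1, "stage2_val_mae": hist2}
        self.n_features_in_ = self.dim
        return self

    def predict_delta(self, smiles: str,
                      core_atoms: Sequence[int]) -> DeltaPrediction:
        """Decomposed prediction for one molecule and core mask."""
        mol = parse_molecule(smiles)
        xc, ctx_rows = self._encoder().encode_masked(mol, core_atoms)
        zc = (xc - self.x_mean_) * self.x_scale_
        zrows = ctx_rows * self.ctx_scale_
        seg = np.zeros(len(zrows), dtype=int)
        core, corr, _, _ = _forward(self.params_, zc[None, :], zrows, seg,
                                    use_ctx=True)
        core_value = self.y_mean_ + self.y_scale_ * float(core[0])
        correction = self.y_scale_ * float(corr[0])
        if len(ctx_rows) == 0:
            # a whole-molecule mask has no context rows; the bias-free
            # summed pathway then returns 0.0 exactly, by construction
            assert correction == 0.0
        return DeltaPrediction(core_value=core_value, correction=correction)

    def predict(self, X: Sequence[str], *,
                core_atoms: Sequence[Sequence[int]]) -> np.ndarray:
        return np.array([self.predict_delta(s, c).total
                         for s, c in zip(X, core_atoms)])


# ---------------------------------------------------------------------------
# splits, metrics, recalibration


@dataclass(frozen=True)
class SplitSpec:
    """Randomized train:validation:test split with cross-validation folds.

    Default 64:16:20 with 5 folds — the validation sets of the folds
    partition the 80% train+validation pool.
    """

    train: int = 64
    validation: int = 16
    test: int = 20
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.train + self.validation + self.test != 100:
            raise ValueError("split fractions must sum to 100")
        if self.n_folds * self.validation != self.train + self.validation:
            raise ValueError(
                "fold validation sets must partition the train+validation "
                f"pool: {self.n_folds} x {self.validation} != "
                f"{self.train + self.validation}")


@dataclass
class Splits:
    test_idx: np.ndarray
    pool_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train, validation)


def make_splits(n: int, spec: SplitSpec = SplitSpec()) -> Splits:
    """Disjoint, exhaustive, seed-reproducible splits of ``range(n)``."""
    if n < spec.n_folds:
        raise ValueError(f"need at least {spec.n_folds} records, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_test = int(round(n * spec.test / 100))
    test_idx = np.sort(perm[:n_test])
    pool = perm[n_test:]
    chunks = np.array_split(pool, spec.n_folds)
    folds = []
    for i in range(spec.n_folds):
        val = np.sort(chunks[i])
        train = np.sort(np.concatenate(
            [chunks[j] for j in range(spec.n_folds) if j != i]))
        folds.append((train, val))
    return Splits(test_idx=test_idx, pool_idx=np.sort(pool), folds=folds)


@dataclass(frozen=True)
class EvalMetrics:
    mae: float
    r2: float  # NaN when the truths have zero variance
    n: int


def evaluate(predictions: Sequence[float],
             truths: Sequence[float]) -> EvalMetrics:
    """MAE (kcal/mol) and coefficient of determination R^2.

    R^2 is undefined (NaN) for zero-variance truths.
    """
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(truths, dtype=float)
    if yhat.shape != y.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("need equal-length 1-d arrays with >= 2 entries")
    mae = float(mean_absolute_error(y, yhat))
    if np.allclose(y, y[0]):
        r2 = float("nan")
    else:
        r2 = float(r2_score(y, yhat))
    return EvalMetrics(mae=mae, r2=r2, n=len(y))


@dataclass(frozen=True)
class RecalibrationResult:
    slope: float
    intercept: float
    mae_before: float
    r2_before: float
    mae_after: float
    r2_after: float


def linear_recalibration(gap_a: Sequence[float],
                         gap_b: Sequence[float]) -> RecalibrationResult:
    """OLS fit mapping method A's gaps onto method B's, with metrics.

    Reports MAE/R^2 of the raw A-vs-B comparison and of the linearly
    corrected values (slope*A + intercept vs B).  The corrected MAE on the
    fitting data is typically, though not axiomatically, smaller.
    """
    a = np.asarray(gap_a, dtype=float)
    b = np.asarray(gap_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    if np.allclose(a, a[0]):
        raise ValueError("degenerate (constant) input")
    fit = stats.linregress(a, b)
    corrected = fit.slope * a + fit.intercept
    before = evaluate(a, b)
    after = evaluate(corrected, b)
    return RecalibrationResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        mae_before=before.mae, r2_before=before.r2,
        mae_after=after.mae, r2_after=after.r2)
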