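import numpy as np
import pytest

import chromofrag as cf
from chromofrag.models import (
    CoreFragmentRegressor, CoreLookupRegressor, CoreMatchError,
    DeltaGapRegressor, LookupMiss, SplitSpec, evaluate,
    linear_recalibration, make_core_mask, make_splits,
)
from chromofrag.molgraph import parse_molecule
from tests.conftest import ALLYLBENZENE


@pytest.fixture(scope="module")
def trained_delta(library_values):
    """A delta model trained briefly on a small noisy oracle dataset."""
    spec = cf.OracleSpec(n=250, seed=13)
    records, truth = cf.generate_molecules(spec)
    frags = sorted(library_values)
    model = DeltaGapRegressor(seed=0, stage1_epochs=200, stage2_epochs=200)
    model.fit([r.smiles for r in records],
              [r.gap for r in records],
              core_atoms=[truth[r.id]["core_atoms"] for r in records],
              fragments=frags,
              fragment_gaps=[library_values[s] for s in frags])
    return model, records, truth


class TestMakeCoreMask:
    def test_toluene_pattern_on_allylbenzene(self):
        mol = parse_molecule(ALLYLBENZENE)
        mask = make_core_mask(mol, "Cc1ccccc1")
        assert len(mask.atom_indices) == 7  # ring + exocyclic CH2
        assert len(mask.bond_indices) == 7

    def test_whole_molecule_pattern(self):
        mol = parse_molecule(ALLYLBENZENE)
        mask = make_core_mask(mol, ALLYLBENZENE)
        assert mask.atom_indices == frozenset(range(mol.GetNumAtoms()))
        assert len(mask.bond_indices) == mol.GetNumBonds()

    def test_no_match_is_an_error(self):
        with pytest.raises(CoreMatchError):
            make_core_mask(parse_molecule("CCCl"), "c1ccccc1")

    def test_multiple_nonequivalent_matches_warn(self):
        mol = parse_molecule("C=CCCCC=C")  # two distinct vinyl matches
        with pytest.warns(UserWarning, match="non-equivalent"):
            make_core_mask(mol, "C=CC")


class TestCoreLookup:
    def test_self_lookup(self):
        lk = CoreLookupRegressor().fit(["c1ccccc1C", "C=CC"], [85.7, 62.4])
        assert lk.lookup("Cc1ccccc1") == 85.7

    def test_miss_raises(self):
        lk = CoreLookupRegressor().fit(["C=CC"], [62.4])
        with pytest.raises(LookupMiss):
            lk.lookup("CC#N")

    def test_noiseless_oracle_lookup_is_exact(self, library_values):
        spec = cf.OracleSpec(n=60, seed=5, sigma_sub=0.0, sigma_obs=0.0)
        records, truth = cf.generate_molecules(spec)
        lk = CoreLookupRegressor().fit(list(library_values),
                                       list(library_values.values()))
        preds = lk.predict([truth[r.id]["core"] for r in records])
        assert np.allclose(preds, [r.gap for r in records])


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mae == 0.0 and m.r2 == 1.0

    def test_constant_predictor_at_mean_has_zero_r2(self):
        y = [1.0, 2.0, 3.0, 6.0]
        m = evaluate([3.0] * 4, y)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_three_point_case(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 1.0, 4.0])
        assert m.mae == pytest.approx(2.0 / 3.0)

    def test_zero_variance_truths_undefined_r2(self):
        m = evaluate([1.0, 2.0], [5.0, 5.0])
        assert np.isnan(m.r2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([1.0], [1.0, 2.0])


class TestMakeSplits:
    def test_100_records_default_spec(self):
        s = make_splits(100)
        assert len(s.test_idx) == 20
        for _, val in s.folds:
            assert len(val) == 16

    def test_partition_properties(self):
        s = make_splits(173, SplitSpec(seed=3))
        assert set(s.test_idx) | set(s.pool_idx) == set(range(173))
        assert not set(s.test_idx) & set(s.pool_idx)
        all_val = np.concatenate([v for _, v in s.folds])
        assert sorted(all_val.tolist()) == sorted(s.pool_idx.tolist())
        for train, val in s.folds:
            assert not set(train) & set(val)
            assert set(train) | set(val) == set(s.pool_idx)

    def test_seed_reproducible(self):
        a = make_splits(50, SplitSpec(seed=9))
        b = make_splits(50, SplitSpec(seed=9))
        assert (a.test_idx == b.test_idx).all()
        assert all((ta == tb).all() and (va == vb).all()
                   for (ta, va), (tb, vb) in zip(a.folds, b.folds))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 100"):
            SplitSpec(train=60, validation=16, test=20)

    def test_folds_must_partition_pool(self):
        with pytest.raises(ValueError, match="partition"):
            SplitSpec(train=70, validation=10, test=20, n_folds=5)


class TestLinearRecalibration:
    def test_identical_pairs(self):
        x = [1.0, 2.0, 3.0]
        fit = linear_recalibration(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_recovery_of_affine_transform(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(40, 100, 200)
        b = 0.9 * a + 2.0 + rng.normal(0, 1.0, 200)
        fit = linear_recalibration(a, b)
        assert fit.slope == pytest.approx(0.9, abs=0.02)
        assert fit.intercept == pytest.approx(2.0, abs=1.5)

    def test_correction_reduces_mae_on_fit_data(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(40, 100, 100)
        b = 0.8 * a + 5.0 + rng.normal(0, 0.5, 100)
        fit = linear_recalibration(a, b)
        assert fit.mae_after <= fit.mae_before

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            linear_recalibration([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestErrorBudget:
    def test_model_plus_cross_method_error_bounds_cross_prediction(
            self, library_values):
        """Predicting method-B labels with an A-trained scheme incurs at
        most (roughly) the A-error plus the A-to-B method discrepancy."""
        spec = cf.OracleSpec(n=400, seed=17)
        records, truth = cf.generate_molecules(spec)
        lk = CoreLookupRegressor().fit(list(library_values),
                                       list(library_values.values()))
        preds = lk.predict([truth[r.id]["core"] for r in records])
        gap_a = np.array([r.gap for r in records])
        gap_b = cf.generate_paired_methods(records, slope=1.0,
                                           intercept=1.5, sigma=2.0,
                                           seed=18)
        mae_model = evaluate(preds, gap_a).mae
        mae_cross_method = evaluate(gap_a, gap_b).mae
        mae_cross_pred = evaluate(preds, gap_b).mae
        assert mae_cross_pred <= mae_model + mae_cross_method + 0.1
        assert mae_cross_pred >= mae_model - 0.1


class TestDeltaModel:
    def test_total_is_core_plus_correction(self, trained_delta):
        model, records, truth = trained_delta
        for rec in records[:20]:
            p = model.predict_delta(rec.smiles,
                                    truth[rec.id]["core_atoms"])
            assert p.total == p.core_value + p.correction

    def test_whole_molecule_mask_zero_correction(self, trained_delta,
                                                 library_values):
        model, _, _ = trained_delta
        for smiles in list(library_values)[:8]:
            n = parse_molecule(smiles).GetNumAtoms()
            p = model.predict_delta(smiles, list(range(n)))
            assert p.correction == 0.0
            assert p.total == p.core_value

    def test_symmetry_equivalent_masks_identical_totals(self, trained_delta):
        model, _, _ = trained_delta
        # p-xylene chain: the two methyl-bearing ring halves are equivalent
        smiles = "Cc1ccc(CCC=C)cc1"
        mol = parse_molecule(smiles)
        matches = mol.GetSubstructMatches(
            parse_molecule("C=CC"), uniquify=True)
        assert len(matches) >= 1
        ref = model.predict_delta(smiles, sorted(matches[0]))
        again = model.predict_delta(smiles, sorted(matches[0]))
        assert again.total == ref.total  # deterministic prediction

    def test_core_atom_listing_order_irrelevant(self, trained_delta):
        model, records, truth = trained_delta
        rec = records[0]
        core = truth[rec.id]["core_atoms"]
        ref = model.predict_delta(rec.smiles, core)
        shuffled = model.predict_delta(rec.smiles, core[::-1])
        assert shuffled.total == ref.total
        assert shuffled.correction == ref.correction

    def test_missing_core_annotation_rejected(self, library_values):
        model = DeltaGapRegressor(stage1_epochs=2, stage2_epochs=2)
        with pytest.raises(ValueError, match="core"):
            model.fit(["C=CCc1ccccc1"], [62.0], core_atoms=[[]],
                      fragments=list(library_values)[:5],
                      fragment_gaps=list(library_values.values())[:5])

    def test_empty_fragment_set_rejected(self):
        model = DeltaGapRegressor(stage1_epochs=2, stage2_epochs=2)
        with pytest.raises(ValueError, match="stage 1"):
            model.fit(["C=CC"], [62.0], core_atoms=[[0, 1, 2]],
                      fragments=[], fragment_gaps=[])

    def test_validation_history_logged(self, trained_delta):
        model, _, _ = trained_delta
        assert len(model.history_["stage1_val_mae"]) == 200
        assert len(model.history_["stage2_val_mae"]) == 200
        assert min(model.history_["stage2_val_mae"]) > 0

    def test_shuffled_label_control(self, library_values):
        """With labels shuffled, held-out error approaches the spread of
        the labels themselves (no structure left to learn)."""
        spec = cf.OracleSpec(n=300, seed=23)
        records, truth = cf.generate_molecules(spec)
        rng = np.random.default_rng(0)
        y = np.array([r.gap for r in records])
        y_shuf = y.copy()
        rng.shuffle(y_shuf)
        frags = sorted(library_values)
        model = DeltaGapRegressor(seed=0, stage1_epochs=150,
                                  stage2_epochs=150)
        model.fit([r.smiles for r in records[:240]], y_shuf[:240],
                  core_atoms=[truth[r.id]["core_atoms"]
                              for r in records[:240]],
                  fragments=frags,
                  fragment_gaps=[library_values[s] for s in frags])
        preds = model.predict(
            [r.smiles for r in records[240:]],
            core_atoms=[truth[r.id]["core_atoms"] for r in records[240:]])
        mae = evaluate(preds, y_shuf[240:]).mae
        spread = np.mean(np.abs(y - y.mean()))
        assert 0.5 * spread < mae < 2.0 * spread


class TestCoreFragmentRegressor:
    def test_fits_small_fragment_set_well_below_label_spread(
            self, library_values):
        frags = sorted(library_values)
        y = np.array([library_values[s] for s in frags])
        model = CoreFragmentRegressor(seed=0, epochs=800)
        model.fit(frags, y)
        mae = evaluate(model.predict(frags), y).mae
        spread = np.mean(np.abs(y - y.mean()))
        assert mae < 0.5 * spread

    def test_distinct_fragments_distinct_predictions(self, library_values):
        frags = sorted(library_values)
        model = CoreFragmentRegressor(seed=0, epochs=300)
        model.fit(frags, [library_values[s] for s in frags])
        preds = model.predict(["C=CC", "CC#N"])
        assert preds[0] != preds[1]
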