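"""PLS-DA fitting, prediction, LV selection by CV, confusion reporting."""

import numpy as np
import pytest

from kakispec.errors import ContractError, ParameterError
from kakispec.plsda import (
    LabelledSpectra,
    PLSDAModel,
    confusion,
    default_recipe,
    plsda_fit,
    plsda_predict,
    select_lv_by_cv,
)
from kakispec.preprocess import Recipe

IDENTITY = Recipe([])


#: class centroids in general position (square corners), so that argmax over
#: four linear score functions can carve out one region per class — classes
#: laid out collinearly are NOT separable by linear PLS-DA, whatever the LVs
CORNERS = {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.0, 1.0), 3: (1.0, 1.0)}


def toy_separable(n_per_class=6, n_features=5, seed=0, noise=0.0):
    """Four linearly separable classes at square corners in features 0-1."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for day in range(4):
        block = np.zeros((n_per_class, n_features))
        block[:, 0], block[:, 1] = CORNERS[day]
        block += rng.normal(0, noise, size=block.shape)
        X.append(block)
        y.extend([day] * n_per_class)
    return LabelledSpectra(np.vstack(X), np.array(y))


class TestFitPredict:
    def test_separable_classes_fit_perfectly(self):
        data = toy_separable()
        model = plsda_fit(data, 2, recipe=IDENTITY)
        assert np.array_equal(plsda_predict(model, data.X), data.y)

    def test_full_lv_pls_equals_least_squares(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 6))
            y = np.tile(np.arange(4), 8)[:30]
            data = LabelledSpectra(X, y)
            model = plsda_fit(data, 6, recipe=IDENTITY)
            Y = np.zeros((30, 4))
            Y[np.arange(30), y] = 1.0
            design = np.column_stack([np.ones(30), X])
            beta = np.linalg.lstsq(design, Y, rcond=None)[0]
            assert np.max(np.abs(design @ beta
                                 - model.decision_scores(X))) < 1e-8

    def test_row_permutation_leaves_coefficients_unchanged(self):
        data = toy_separable(noise=0.3, seed=2)
        perm = np.random.default_rng(3).permutation(data.n)
        m1 = plsda_fit(data, 3, recipe=IDENTITY)
        m2 = plsda_fit(data.subset(perm), 3, recipe=IDENTITY)
        assert np.max(np.abs(m1.coef - m2.coef)) < 1e-10

    def test_predicting_training_matrix_is_stable(self):
        data = toy_separable(noise=0.2, seed=4)
        model = plsda_fit(data, 2, recipe=IDENTITY)
        p1 = plsda_predict(model, data.X)
        p2 = plsda_predict(model, data.X)
        assert np.array_equal(p1, p2)

    def test_class_centroid_classifies_to_its_class(self):
        data = toy_separable(noise=0.05, seed=5)
        model = plsda_fit(data, 2, recipe=IDENTITY)
        centroid = data.X[data.y == 0].mean(axis=0, keepdims=True)
        assert plsda_predict(model, centroid)[0] == 0

    def test_all_zero_spectrum_yields_valid_label(self):
        data = toy_separable(n_features=10, noise=0.1, seed=6)
        model = plsda_fit(data, 2, recipe=default_recipe())
        label = plsda_predict(model, np.zeros((1, 10)))[0]
        assert label in (0, 1, 2, 3)

    def test_missing_class_rejected(self):
        data = toy_separable()
        keep = data.y != 3
        with pytest.raises(ContractError):
            plsda_fit(data.subset(keep), 1, recipe=IDENTITY)

    def test_lv_bounds_enforced(self):
        data = toy_separable()
        with pytest.raises(ParameterError):
            plsda_fit(data, 25, recipe=IDENTITY)

    def test_prediction_invariant_to_positive_affine_rescale_with_snv(self):
        data = toy_separable(n_features=12, noise=0.2, seed=7)
        model = plsda_fit(data, 3, recipe=default_recipe())
        rng = np.random.default_rng(8)
        Xnew = data.X + rng.normal(0, 0.05, data.X.shape)
        p_base = plsda_predict(model, Xnew)
        p_scaled = plsda_predict(model, 3.7 * Xnew + 0.4)
        assert np.array_equal(p_base, p_scaled)

    def test_save_load_round_trip(self, tmp_path):
        data = toy_separable(noise=0.2, seed=9)
        model = plsda_fit(data, 2, recipe=default_recipe())
        path = str(tmp_path / "model.npz")
        model.save(path)
        clone = PLSDAModel.load(path)
        assert np.array_equal(plsda_predict(clone, data.X),
                              plsda_predict(model, data.X))


def brute_force_cv_curve(data, max_lv, folds, seed, recipe):
    """Independent re-computation of the CV misclassification curve."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    curve = []
    for lv in range(1, max_lv + 1):
        wrong = 0
        for tr, va in skf.split(data.X, data.y):
            m = plsda_fit(data.subset(tr), lv, recipe=recipe)
            wrong += int((plsda_predict(m, data.X[va]) != data.y[va]).sum())
        curve.append(wrong / data.n)
    return np.array(curve)


class TestLVSelection:
    def test_separable_data_reaches_zero_cv_error(self):
        data = toy_separable(n_per_class=10, noise=0.01, seed=10)
        n_lv, curve = select_lv_by_cv(data, 4, folds=5, seed=0,
                                      recipe=IDENTITY)
        assert curve[n_lv - 1] == 0.0

    def test_deterministic_given_seed(self):
        data = toy_separable(n_per_class=10, noise=0.5, seed=11)
        r1 = select_lv_by_cv(data, 5, folds=5, seed=3, recipe=IDENTITY)
        r2 = select_lv_by_cv(data, 5, folds=5, seed=3, recipe=IDENTITY)
        assert r1[0] == r2[0]
        assert np.array_equal(r1[1], r2[1])

    def test_matches_brute_force_recomputation(self):
        data = toy_separable(n_per_class=8, noise=0.6, seed=12)
        n_lv, curve = select_lv_by_cv(data, 5, folds=4, seed=7,
                                      recipe=IDENTITY)
        oracle = brute_force_cv_curve(data, 5, 4, 7, IDENTITY)
        assert np.allclose(curve, oracle)
        assert n_lv == int(np.argmin(oracle)) + 1

    def test_selected_lv_minimises_curve(self):
        data = toy_separable(n_per_class=8, noise=0.8, seed=13)
        n_lv, curve = select_lv_by_cv(data, 5, folds=4, seed=1,
                                      recipe=IDENTITY)
        assert np.all(curve[n_lv - 1] <= curve)

    def test_fold_count_reduced_for_small_classes(self):
        data = toy_separable(n_per_class=3, noise=0.1, seed=14)
        n_lv, curve = select_lv_by_cv(data, 2, folds=10, seed=0,
                                      recipe=IDENTITY)
        assert curve.size == 2   # ran despite classes smaller than folds


class TestConfusion:
    def test_perfect_predictions(self):
        rep = confusion([0, 1, 2, 3, 2], [0, 1, 2, 3, 2])
        assert np.trace(rep.counts) == 5
        assert rep.total_pct == 100.0
        assert np.all(rep.per_class_pct == 100.0)

    def test_hand_counted_example(self):
        rep = confusion([0, 0, 1], [0, 1, 1])
        assert rep.counts[0, 0] == 1 and rep.counts[0, 1] == 1
        assert rep.per_class_pct[0] == 50.0
        assert rep.per_class_pct[1] == 100.0
        assert abs(rep.total_pct - 200.0 / 3.0) < 1e-9

    def test_percentages_consistent_with_counts(self):
        rng = np.random.default_rng(15)
        t = rng.integers(0, 4, 100)
        p = rng.integers(0, 4, 100)
        rep = confusion(t, p)
        assert rep.counts.sum() == 100
        for c in range(4):
            row = rep.counts[c]
            assert row.sum() == np.count_nonzero(t == c)
            if row.sum():
                assert rep.per_class_pct[c] == 100.0 * row[c] / row.sum()

    def test_label_outside_range_rejected(self):
        with pytest.raises(ContractError):
            confusion([0, 4], [0, 0])
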