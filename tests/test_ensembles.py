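"""Combining techniques: weights, votes, meta-dataset, beta search."""

import collections

import numpy as np
import pytest

import rxclassify as rx
from rxclassify.ensembles import (
    MetaDataset,
    StackingEnsemble,
    VotingEnsemble,
    WeightedVotingEnsemble,
    build_meta_dataset,
    fold_aligned_vote,
    learn_weights,
    majority_vote,
    stack_fit_predict,
    tune_beta,
    vote,
    weighted_vote,
)
from rxclassify.learners import make_spec

from conftest import random_prediction_problem


def oracle_majority(row):
    """Independent plain-majority oracle: most votes, lowest label on ties."""
    counts = collections.Counter(int(v) for v in row)
    top = max(counts.values())
    return min(label for label, c in counts.items() if c == top)


class TestLearnWeights:
    def test_closed_form_beta_power_errors(self, rng):
        for _ in range(50):
            P, y, _ = random_prediction_problem(rng)
            beta = float(rng.uniform(0.05, 1.0))
            w = learn_weights(P, y, beta)
            errors = (P != y[:, None]).sum(axis=0)
            assert np.array_equal(w.error_counts, errors)
            assert np.allclose(w.weights, beta ** errors.astype(float), atol=1e-12)

    def test_beta_one_gives_unit_weights(self, rng):
        P, y, _ = random_prediction_problem(rng)
        assert (learn_weights(P, y, 1.0).weights == 1.0).all()

    def test_single_error_halves_weight(self):
        P = np.array([[1, 1], [1, 2], [1, 1]])
        y = np.array([1, 1, 1])
        w = learn_weights(P, y, 0.5)
        assert w.weights.tolist() == [1.0, 0.5]

    def test_error_free_classifier_keeps_weight_one(self, rng):
        P, y, _ = random_prediction_problem(rng)
        P[:, 0] = y
        assert learn_weights(P, y, 0.3).weights[0] == 1.0

    def test_anti_monotone_ordering(self, rng):
        for _ in range(20):
            P, y, _ = random_prediction_problem(rng, n_classifiers_max=6)
            w = learn_weights(P, y, 0.8)
            order = np.argsort(w.error_counts, kind="stable")
            sorted_weights = w.weights[order]
            assert (np.diff(sorted_weights) <= 1e-15).all()

    @pytest.mark.parametrize("beta", [0.0, -0.5, 1.5])
    def test_invalid_beta_rejected(self, beta, rng):
        P, y, _ = random_prediction_problem(rng)
        with pytest.raises(ValueError):
            learn_weights(P, y, beta)


class TestVote:
    def test_unanimous_row_wins_for_any_weights(self, rng):
        w = rng.uniform(0.1, 1.0, size=4)
        assert vote([3, 3, 3, 3], w) == 3

    def test_equal_weights_majority(self):
        assert vote([1, 1, 2]) == 1

    def test_heavy_classifier_outvotes_pair(self):
        assert vote([2, 1, 1], np.array([3.0, 1.0, 1.0])) == 2

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            vote([])

    def test_tie_goes_to_heaviest_single_voter(self):
        # classes 1 and 2 both sum to 1.0; class 2 holds the heaviest voter
        assert vote([1, 1, 2], np.array([0.5, 0.5, 1.0])) == 2

    def test_residual_tie_goes_to_lowest_class(self):
        assert vote([2, 1], np.array([1.0, 1.0])) == 1

    def test_unit_beta_equals_plain_majority(self, rng):
        for _ in range(200):
            P, y, _ = random_prediction_problem(rng)
            w = learn_weights(P, y, 1.0)
            combined = weighted_vote(P, w)
            expected = np.array([oracle_majority(row) for row in P])
            assert np.array_equal(combined, expected)


@pytest.fixture(scope="module")
def tiny_problem():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 4))
    y = np.array([1, 2] * 5)
    X[y == 2] += 3.0
    return X, y


class TestMetaDataset:
    def test_shape_and_fold_sizes(self, tiny_problem):
        X, y = tiny_problem
        specs = [make_spec("knn"), make_spec("naive_bayes"), make_spec("decision_tree")]
        meta = build_meta_dataset(specs, X, y, J=5, seed=0)
        assert meta.predictions.shape == (10, 3)
        assert meta.to_frame().shape == (10, 5)  # N predictions + actual + fold
        assert np.bincount(meta.fold).tolist() == [2] * 5

    def test_no_row_predicted_by_its_own_training_model(self, tiny_problem):
        X, y = tiny_problem
        meta = build_meta_dataset([make_spec("knn")], X, y, J=5, seed=1)
        meta.assert_no_leakage()

    def test_leakage_audit_detects_corruption(self, tiny_problem):
        X, y = tiny_problem
        meta = build_meta_dataset([make_spec("knn")], X, y, J=5, seed=1)
        bad_fold = meta.fold[0]
        meta.train_indices[bad_fold] = np.arange(len(y))
        with pytest.raises(AssertionError):
            meta.assert_no_leakage()

    def test_same_seed_same_folds(self, tiny_problem):
        X, y = tiny_problem
        m1 = build_meta_dataset([make_spec("knn")], X, y, J=5, seed=3)
        m2 = build_meta_dataset([make_spec("knn")], X, y, J=5, seed=3)
        assert np.array_equal(m1.fold, m2.fold)
        assert np.array_equal(m1.predictions, m2.predictions)

    def test_too_many_folds_rejected(self, tiny_problem):
        X, y = tiny_problem
        with pytest.raises(ValueError):
            build_meta_dataset([make_spec("knn")], X, y, J=11, seed=0)

    def test_perfect_base_learners_fill_truth_columns(self, separable_Xy):
        X, y = separable_Xy
        meta = build_meta_dataset([make_spec("knn")], X, y, J=5, seed=0)
        assert np.array_equal(meta.predictions[:, 0], y)


class TestStacking:
    def test_truth_meta_features_predict_perfectly(self, rng):
        y = rng.integers(1, 5, size=30)
        meta = MetaDataset(
            predictions=y[:, None].repeat(2, axis=1),
            y=y,
            fold=np.zeros(30, dtype=int),
            classifier_names=["a", "b"],
        )
        preds = stack_fit_predict(meta, y[:, None].repeat(2, axis=1))
        assert np.array_equal(preds, y)

    def test_three_identical_rows_predict_their_label(self):
        meta = MetaDataset(
            predictions=np.array([[2], [2], [2]]),
            y=np.array([4, 4, 4]),
            fold=np.zeros(3, dtype=int),
            classifier_names=["a"],
        )
        assert stack_fit_predict(meta, np.array([[2]]))[0] == 4

    def test_dimension_mismatch_rejected(self):
        meta = MetaDataset(
            predictions=np.array([[1], [2]]),
            y=np.array([1, 2]),
            fold=np.array([0, 1]),
            classifier_names=["a"],
        )
        with pytest.raises(ValueError):
            stack_fit_predict(meta, np.array([[1, 2]]))

    def test_stacked_cv_is_perfect_on_separable_data(self, separable_Xy):
        X, y = separable_Xy
        specs = [make_spec("knn"), make_spec("decision_tree"), make_spec("naive_bayes")]
        meta = build_meta_dataset(specs, X, y, J=5, seed=0)
        preds = stack_fit_predict(meta, meta.predictions)
        assert (preds == y).mean() == 1.0


class TestTuneBeta:
    def test_singleton_grid_returns_plain_voting(self, separable_Xy):
        X, y = separable_Xy
        specs = [make_spec("knn"), make_spec("naive_bayes")]
        res = tune_beta(specs, X, y, grid=[1.0], cv_folds=5, seed=0)
        assert res.best_beta == 1.0
        assert res.table.shape == (1, 2)

    def test_separable_data_ties_resolve_to_largest_beta(self, separable_Xy):
        X, y = separable_Xy
        specs = [make_spec("knn"), make_spec("decision_tree")]
        res = tune_beta(specs, X, y, grid=[0.5, 0.75, 1.0], cv_folds=5, seed=0)
        assert res.best_beta == 1.0
        assert np.allclose(res.table["accuracy"], 1.0)

    def test_grid_order_irrelevant(self, separable_Xy):
        X, y = separable_Xy
        specs = [make_spec("knn"), make_spec("naive_bayes")]
        meta = build_meta_dataset(specs, X, y, J=5, seed=2)
        a = tune_beta(specs, X, y, grid=[0.3, 0.9, 0.6], cv_folds=5, seed=2, meta=meta)
        b = tune_beta(specs, X, y, grid=[0.9, 0.6, 0.3], cv_folds=5, seed=2, meta=meta)
        assert a.best_beta == b.best_beta

    @pytest.mark.parametrize("grid", [[], [0.0, 0.5], [1.2]])
    def test_invalid_grids_rejected(self, grid, separable_Xy):
        X, y = separable_Xy
        with pytest.raises(ValueError):
            tune_beta([make_spec("knn")], X, y, grid=grid, cv_folds=5, seed=0)


class TestEnsembleEstimators:
    def test_voting_ensemble_is_weighted_with_unit_beta(self, separable_Xy):
        X, y = separable_Xy
        specs = [make_spec("knn"), make_spec("naive_bayes"), make_spec("decision_tree")]
        clf = VotingEnsemble(base_specs=specs).fit(X, y)
        assert clf.beta == 1.0
        assert (clf.predict(X) == y).mean() == 1.0

    def test_weighted_voting_ensemble_learns_out_of_fold_weights(self, separable_Xy):
        X, y = separable_Xy
        specs = [make_spec("knn"), make_spec("naive_bayes")]
        clf = WeightedVotingEnsemble(base_specs=specs, beta=0.9, inner_folds=4).fit(X, y)
        assert np.allclose(clf.weights_.weights, 0.9 ** clf.weights_.error_counts)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_stacking_ensemble_fit_predict(self, separable_Xy):
        X, y = separable_Xy
        specs = [make_spec("knn"), make_spec("decision_tree")]
        clf = StackingEnsemble(base_specs=specs, inner_folds=4).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_fold_aligned_vote_matches_plain_majority_at_unit_beta(self, separable_Xy):
        X, y = separable_Xy
        specs = [make_spec("knn"), make_spec("naive_bayes"), make_spec("decision_tree")]
        meta = build_meta_dataset(specs, X, y, J=5, seed=4)
        assert np.array_equal(
            fold_aligned_vote(meta, 1.0), majority_vote(meta.predictions)
        )
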