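"""Regularized random forest: folds, training, tuning, cross-validation."""

import numpy as np
import pytest
from scipy import stats

from sfcquant.ie_model import (
    RRFHyperparams,
    cross_validated_predictions,
    make_folds_rank_stratified,
    train_rrf,
    tune_hyperparameters,
)
from sfcquant import SynthConfig, generate_dataset


class TestRankStratifiedFolds:
    def test_ten_singletons_when_n_equals_k(self, rng):
        folds = make_folds_rank_stratified(rng.normal(size=10), k=10, seed=0)
        assert sorted(folds) == list(range(10))

    def test_partition_and_balanced_sizes_at_n127(self, rng):
        y = rng.normal(size=127)
        folds = make_folds_rank_stratified(y, k=10, seed=3)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.sum() == 127
        assert set(sizes) <= {12, 13}

    def test_each_fold_spans_the_distribution(self, rng):
        y = rng.normal(size=127)
        folds = make_folds_rank_stratified(y, k=10, seed=5)
        ranks = stats.rankdata(y)
        global_mean = ranks.mean()
        for f in range(10):
            assert abs(ranks[folds == f].mean() - global_mean) <= 10

    def test_too_few_chemicals_rejected(self):
        with pytest.raises(ValueError):
            make_folds_rank_stratified(np.arange(5.0), k=10)


def _toy_problem(rng, n=80, p=12, informative=(0, 3), noise=0.0):
    X = rng.normal(size=(n, p))
    y = sum(X[:, j] * (j + 1.0) for j in informative) + noise * rng.normal(size=n)
    return X, y


class TestTrainRRF:
    def test_mtry_exceeding_descriptors_rejected(self, rng):
        X, y = _toy_problem(rng)
        with pytest.raises(ValueError, match="mtry"):
            train_rrf(X, y, RRFHyperparams(mtry=13, n_trees=5))

    def test_noiseless_deep_trees_interpolate_training_data(self, rng):
        # full-sample trees (no bootstrap) grown to purity must interpolate
        X, y = _toy_problem(rng, informative=(0,))
        model = train_rrf(
            X, y, RRFHyperparams(mtry=12, coef_imp=0.0, n_trees=20, min_node=1),
            seed=1, bootstrap=False,
        )
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 1e-6

    def test_prediction_is_mean_over_trees(self, rng):
        X, y = _toy_problem(rng, noise=0.5)
        model = train_rrf(X, y, RRFHyperparams(mtry=6, n_trees=12), seed=2)
        per_tree = np.stack([t.predict(X) for t in model.trees])
        np.testing.assert_allclose(model.predict(X), per_tree.mean(axis=0), rtol=1e-12)

    def test_column_order_invariance_with_full_mtry(self, rng):
        # with mtry = p the candidate set is every feature at every split, so
        # predictions must not depend on descriptor column order
        X, y = _toy_problem(rng, noise=0.3)
        hyper = RRFHyperparams(mtry=12, coef_imp=0.0, n_trees=25)
        ref = train_rrf(X, y, hyper, seed=4).predict(X)
        perm = rng.permutation(X.shape[1])
        out = train_rrf(X[:, perm], y, hyper, seed=4).predict(X[:, perm])
        np.testing.assert_allclose(ref, out, rtol=1e-10)

    def test_planted_features_dominate_importances(self):
        # sparse signal recovery: planted informative descriptors should fill
        # most of the top-10 importance slots, averaged over seeded draws
        hits = []
        for seed in range(5):
            ds = generate_dataset(SynthConfig(seed=100 + seed))
            X = ds.descriptor_matrix.to_numpy()
            model = train_rrf(
                X, ds.truth.log_rf, RRFHyperparams(mtry=86, coef_reg=1.0, coef_imp=0.5, n_trees=60),
                seed=seed,
            )
            top10 = set(model.top_features(10).tolist())
            hits.append(len(top10 & set(ds.truth.informative_indices.tolist())))
        assert np.mean(hits) >= 4

    def test_used_features_recorded(self, rng):
        X, y = _toy_problem(rng, informative=(0,))
        model = train_rrf(X, y, RRFHyperparams(mtry=12, coef_reg=0.05, coef_imp=0.0, n_trees=20), seed=0)
        assert model.used_features
        assert model.used_features <= set(range(X.shape[1]))
        assert 0 in model.used_features


class TestCrossValidation:
    def test_every_chemical_predicted_exactly_once(self, rng):
        X, y = _toy_problem(rng, noise=0.5)
        folds = make_folds_rank_stratified(y, k=5, seed=0)
        preds = cross_validated_predictions(X, y, RRFHyperparams(mtry=6, n_trees=15), folds, seed=0)
        assert preds.shape == y.shape
        assert np.isfinite(preds).all()

    def test_strong_signal_gives_high_out_of_fold_rho(self, rng):
        X, y = _toy_problem(rng, n=120, noise=0.0)
        folds = make_folds_rank_stratified(y, k=10, seed=1)
        preds = cross_validated_predictions(
            X, y, RRFHyperparams(mtry=12, coef_imp=0.0, n_trees=60, min_node=2), folds, seed=1
        )
        assert stats.spearmanr(preds, y).statistic >= 0.9

    def test_constant_target_predicted_exactly(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.full(40, 3.25)
        folds = make_folds_rank_stratified(y, k=4, seed=0)
        preds = cross_validated_predictions(X, y, RRFHyperparams(mtry=3, n_trees=10), folds, seed=0)
        np.testing.assert_allclose(preds, 3.25)

    def test_own_fold_poisoning_does_not_leak(self, rng):
        X, y = _toy_problem(rng, noise=0.3)
        folds = make_folds_rank_stratified(y, k=4, seed=2)
        hyper = RRFHyperparams(mtry=6, coef_imp=0.0, n_trees=15)
        ref = cross_validated_predictions(X, y, hyper, folds, seed=3)
        poisoned = y.copy()
        poisoned[folds == 0] = 1e6  # sentinel
        out = cross_validated_predictions(X, poisoned, hyper, folds, seed=3)
        np.testing.assert_allclose(out[folds == 0], ref[folds == 0], rtol=1e-10)


class TestTuning:
    def test_single_point_grid_returned(self, rng):
        X, y = _toy_problem(rng)
        h = RRFHyperparams(mtry=4, n_trees=8)
        assert tune_hyperparameters(X, y, [h], seed=0) is h

    def test_dense_signal_prefers_plain_forest(self, rng):
        # every descriptor informative -> heavy feature regularization hurts
        n, p = 90, 15
        X = rng.normal(size=(n, p))
        y = X @ rng.uniform(0.5, 1.5, size=p)
        plain = RRFHyperparams(mtry=10, coef_reg=1.0, coef_imp=0.0, n_trees=40)
        sparse = RRFHyperparams(mtry=10, coef_reg=0.01, coef_imp=0.0, n_trees=40)
        assert tune_hyperparameters(X, y, [plain, sparse], seed=1) is plain

    def test_deterministic_given_seed(self, rng):
        X, y = _toy_problem(rng, noise=1.0)
        grid = [RRFHyperparams(mtry=3, n_trees=10), RRFHyperparams(mtry=8, n_trees=10)]
        a = tune_hyperparameters(X, y, grid, seed=7)
        b = tune_hyperparameters(X, y, grid, seed=7)
        assert a is b

    def test_empty_grid_rejected(self, rng):
        X, y = _toy_problem(rng)
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, [], seed=0)
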