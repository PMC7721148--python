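"""Sparse logistic ensemble: penalty grid, solver, undersampling, nested CV."""

import numpy as np
import pytest

from mddnet import classify, evaluate, synth
from mddnet.classify import logistic_objective


def fista_lasso_logistic(X, y, lam, iters=20000):
    """Independent accelerated proximal-gradient oracle for the L1 objective."""
    n, p = X.shape
    w = np.zeros(p)
    b = 0.0
    wz, bz, t = w.copy(), b, 1.0
    L = np.linalg.norm(np.column_stack([X, np.ones(n)]), 2) ** 2 / (4 * n)
    for _ in range(iters):
        g = 1 / (1 + np.exp(-(X @ wz + bz))) - y
        wn = wz - (X.T @ g / n) / L
        bn = bz - g.mean() / L
        wn = np.sign(wn) * np.maximum(np.abs(wn) - lam / L, 0)
        tn = (1 + np.sqrt(1 + 4 * t * t)) / 2
        wz = wn + (t - 1) / tn * (wn - w)
        bz = bn + (t - 1) / tn * (bn - b)
        w, b, t = wn, bn, tn
    return classify.SparseLogisticModel(w=w, intercept=b, lambda_selected=lam,
                                        feature_mean=np.zeros(p), feature_scale=np.ones(p))


@pytest.fixture(scope="module")
def random_instance():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 5))
    y = (rng.random(20) < 0.5).astype(int)
    return X, y


class TestLambdaGrid:
    def test_all_zero_exactly_at_lambda_max(self, random_instance):
        X, y = random_instance
        lmax = classify.lambda_max(X, y)
        model = classify.fit_sparse_logistic(X, y, lmax)
        assert np.all(model.w == 0)
        assert model.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())))

    def test_nonzero_weight_below_lambda_max(self, random_instance):
        X, y = random_instance
        lmax = classify.lambda_max(X, y)
        model = classify.fit_sparse_logistic(X, y, 0.9 * lmax)
        assert (model.w != 0).any()
        # oracle agreement at 0.9 lambda_max
        oracle = fista_lasso_logistic(X, y, 0.9 * lmax)
        assert (logistic_objective(model, X, y, 0.9 * lmax)
                == pytest.approx(logistic_objective(oracle, X, y, 0.9 * lmax), abs=1e-4))

    def test_grid_has_requested_points_from_zero_to_max(self, random_instance):
        X, y = random_instance
        grid = classify.lambda_grid(X, y, 25)
        assert grid.size == 25
        assert grid[0] == pytest.approx(classify.lambda_max(X, y))
        assert grid[-1] == 0
        np.testing.assert_allclose(np.diff(grid), np.diff(grid)[0])

    def test_row_duplication_leaves_lambda_max_unchanged(self, random_instance):
        X, y = random_instance
        assert classify.lambda_max(np.vstack([X, X]), np.concatenate([y, y])) == \
            pytest.approx(classify.lambda_max(X, y))

    def test_single_class_rejected(self, random_instance):
        X, _ = random_instance
        with pytest.raises(ValueError):
            classify.lambda_max(X, np.ones(20, dtype=int))


class TestFitSparseLogistic:
    def test_objective_matches_fista_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(3):
            X = rng.normal(size=(20, 5))
            y = np.array([0, 1] * 10)[rng.permutation(20)]
            lam = 0.1
            model = classify.fit_sparse_logistic(X, y, lam)
            oracle = fista_lasso_logistic(X, y, lam)
            assert (logistic_objective(model, X, y, lam)
                    == pytest.approx(logistic_objective(oracle, X, y, lam), abs=1e-4))

    def test_separable_toy_perfect_at_zero_penalty(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = classify.fit_sparse_logistic(X, y, 0.0)
        assert np.all((model.predict_proba(X) > 0.5) == y)

    def test_selected_indices_are_nonzero_support(self, random_instance):
        X, y = random_instance
        model = classify.fit_sparse_logistic(X, y, 0.3 * classify.lambda_max(X, y))
        np.testing.assert_array_equal(model.selected_indices, np.flatnonzero(model.w))

    def test_negative_penalty_rejected(self, random_instance):
        X, y = random_instance
        with pytest.raises(ValueError):
            classify.fit_sparse_logistic(X, y, -0.1)


class TestUndersampling:
    def test_balanced_identical_ages_selects_everyone(self):
        age = np.concatenate([np.arange(20.0, 40.0), np.arange(20.0, 40.0)])
        y = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        subset = classify.undersample_age_matched(y, age, seed=0)
        assert subset.size == 40
        assert abs(age[subset][y[subset] == 0].mean() - age[subset][y[subset] == 1].mean()) == 0

    def test_imbalanced_classes_balanced_within_tolerance(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([np.zeros(200, int), np.ones(100, int)])
        age = rng.normal(45, 12, size=300)
        subset = classify.undersample_age_matched(y, age, seed=3)
        ys, ages = y[subset], age[subset]
        assert (ys == 0).sum() == (ys == 1).sum() == 100
        assert abs(ages[ys == 0].mean() - ages[ys == 1].mean()) <= 1.0

    def test_cap_limits_subset_size(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([np.zeros(300, int), np.ones(300, int)])
        age = rng.normal(45, 5, size=600)
        subset = classify.undersample_age_matched(y, age, seed=5, cap=125)
        assert subset.size == 250

    def test_same_seed_same_subset(self):
        rng = np.random.default_rng(6)
        y = (rng.random(120) < 0.4).astype(int)
        age = rng.normal(50, 10, size=120)
        a = classify.undersample_age_matched(y, age, seed=7)
        b = classify.undersample_age_matched(y, age, seed=7)
        np.testing.assert_array_equal(a, b)


class TestInnerCV:
    def test_single_value_grid_selected(self, random_instance):
        X, y = random_instance
        assert classify.inner_cv_select_lambda(X, y, np.array([0.05]), k_inner=2) == 0.05

    def test_flat_error_curve_selects_largest(self):
        # pure-noise features: CV error is flat-ish, one-SE rule pushes to
        # maximal shrinkage, i.e. the largest grid value
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 5)) * 1e-3
        y = np.array([0, 1] * 30)
        grid = classify.lambda_grid(X, y, 10)
        lam = classify.inner_cv_select_lambda(X, y, grid, k_inner=5, seed=0)
        assert lam == pytest.approx(grid.max())

    def test_dominant_feature_selected(self):
        rng = np.random.default_rng(9)
        hits = 0
        for rep in range(10):
            n = 120
            y = np.array([0, 1] * (n // 2))
            X = rng.normal(size=(n, 8))
            X[:, 3] += 2.0 * y  # one connection fully determines class
            grid = classify.lambda_grid(X, y, 15)
            lam = classify.inner_cv_select_lambda(X, y, grid, k_inner=5, seed=rep)
            model = classify.fit_sparse_logistic(X, y, lam)
            hits += 3 in model.selected_indices
        assert hits >= 9

    def test_empty_grid_rejected(self, random_instance):
        X, y = random_instance
        with pytest.raises(ValueError):
            classify.inner_cv_select_lambda(X, y, np.array([]))


@pytest.fixture(scope="module")
def trained(signal_dataset):
    _, data = signal_dataset
    ens = classify.train_ensemble(data, outer_folds=5, subsamples=2, seed=0,
                                  n_lambda=15, k_inner=5)
    return data, ens


class TestEnsemble:
    def test_model_count_is_folds_times_subsamples(self, trained):
        _, ens = trained
        assert ens.n_models == 10

    def test_every_participant_assigned_one_fold(self, trained):
        data, ens = trained
        assert (ens.fold_assignment >= 0).all()
        assert np.isfinite(ens.cv_probabilities).all()

    def test_signal_recovered_from_held_out_folds(self, trained):
        data, ens = trained
        assert evaluate.roc_auc(data.y, ens.cv_probabilities) >= 0.85

    def test_sparsity_of_selected_supports(self, trained):
        # at this fixture scale the 10 true connections are already 17% of
        # the 60 features; assert the support stays near that order rather
        # than growing toward the full feature count
        _, ens = trained
        sizes = [m.selected_indices.size for m in ens.flat_models()]
        assert np.median(sizes) <= 25  # ~2.5x the true support, << 60

    def test_determinism(self, signal_dataset):
        _, data = signal_dataset
        a = classify.train_ensemble(data, outer_folds=3, subsamples=2, seed=5,
                                    n_lambda=10, k_inner=3)
        b = classify.train_ensemble(data, outer_folds=3, subsamples=2, seed=5,
                                    n_lambda=10, k_inner=3)
        np.testing.assert_array_equal(a.cv_probabilities, b.cv_probabilities)

    def test_no_leakage_from_held_out_participants(self, signal_dataset):
        # corrupting the held-out fold's connectivity must leave every
        # member model untouched: the fold never enters training
        _, data = signal_dataset
        ens = classify.train_ensemble(data, outer_folds=3, subsamples=2, seed=5,
                                      n_lambda=10, k_inner=3)
        fold0 = ens.fold_assignment == 0
        corrupted = data.connectivity.copy()
        corrupted[fold0] = np.random.default_rng(1).normal(scale=50, size=(fold0.sum(),
                                                                           data.n_fc))
        data2 = synth.MultiSiteDataset(connectivity=corrupted,
                                       phenotypes=data.phenotypes.copy())
        ens2 = classify.train_ensemble(data2, outer_folds=3, subsamples=2, seed=5,
                                       n_lambda=10, k_inner=3)
        for m1, m2 in zip(ens.models[0], ens2.models[0]):
            np.testing.assert_array_equal(m1.w, m2.w)
            assert m1.intercept == m2.intercept
            assert m1.lambda_selected == m2.lambda_selected


class TestPrediction:
    def test_all_zero_members_give_half(self):
        member = classify.SparseLogisticModel(w=np.zeros(4), intercept=0.0,
                                              lambda_selected=1.0,
                                              feature_mean=np.zeros(4),
                                              feature_scale=np.ones(4))
        ens = classify.ClassifierEnsemble(models=[[member, member]],
                                          fold_assignment=np.zeros(1, int), seed=0)
        np.testing.assert_allclose(
            classify.predict_probability(ens, np.random.default_rng(0).normal(size=(5, 4))),
            0.5)

    def test_single_member_equals_member_output(self, random_instance):
        X, y = random_instance
        model = classify.fit_sparse_logistic(X, y, 0.05)
        ens = classify.ClassifierEnsemble(models=[[model]],
                                          fold_assignment=np.zeros(20, int), seed=0)
        np.testing.assert_allclose(classify.predict_probability(ens, X),
                                   model.predict_proba(X))

    def test_monotone_in_positively_weighted_feature(self):
        members = []
        rng = np.random.default_rng(11)
        for _ in range(5):
            w = rng.random(3) * 0.5
            w[1] = 0.8 + rng.random()  # strictly positive weight on feature 1
            members.append(classify.SparseLogisticModel(
                w=w, intercept=float(rng.normal()), lambda_selected=0.1,
                feature_mean=np.zeros(3), feature_scale=np.ones(3)))
        ens = classify.ClassifierEnsemble(models=[members],
                                          fold_assignment=np.zeros(1, int), seed=0)
        base = np.array([[0.2, 0.0, -0.1]])
        grid = np.linspace(-2, 2, 15)
        probs = [classify.predict_probability(
            ens, base + np.array([[0, g, 0]]))[0] for g in grid]
        assert np.all(np.diff(probs) > 0)

    def test_dimension_mismatch_rejected(self, random_instance):
        X, y = random_instance
        model = classify.fit_sparse_logistic(X, y, 0.05)
        ens = classify.ClassifierEnsemble(models=[[model]],
                                          fold_assignment=np.zeros(20, int), seed=0)
        with pytest.raises(ValueError):
            classify.predict_probability(ens, X[:, :3])
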