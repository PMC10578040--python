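"""Splitting, SMOTE, training/evaluation, centroid transfer, attribution."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lupus_endotypes import classify as clf
from lupus_endotypes.simulate import default_activation, simulate_scores


class TestSplit:
    def test_paper_scale_sizes(self):
        # 80/20 of 2183 -> 1746 / 437
        rng = np.random.default_rng(0)
        y = rng.integers(0, 8, 2183)
        tr, val = clf.split_train_validation(range(2183), y, 0.8, seed=1)
        assert (len(tr), len(val)) == (1746, 437)
        assert set(tr).isdisjoint(val)
        assert len(set(tr) | set(val)) == 2183

    def test_small_split_and_stratification(self):
        y = np.array([0] * 5 + [1] * 5)
        tr, val = clf.split_train_validation(range(10), y, 0.8, seed=0)
        assert (len(tr), len(val)) == (8, 2)
        assert sorted(y[list(val)]) == [0, 1]

    def test_same_seed_same_split(self):
        y = np.array([0] * 30 + [1] * 20)
        a = clf.split_train_validation(range(50), y, 0.8, seed=7)
        b = clf.split_train_validation(range(50), y, 0.8, seed=7)
        assert a == b


class TestSmote:
    def test_balances_counts_with_synthetic_points(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(5, 1, (20, 4))])
        y = np.array([0] * 100 + [1] * 20)
        Xb, yb = clf.smote_oversample(X, y, seed=0)
        assert (yb == 0).sum() == 100 and (yb == 1).sum() == 100
        assert len(yb) == 200  # 80 synthetic points appended

    def test_synthetic_points_in_minority_bounding_box(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.uniform(0, 1, (60, 3)), rng.uniform(4, 5, (12, 3))])
        y = np.array([0] * 60 + [1] * 12)
        Xb, yb = clf.smote_oversample(X, y, seed=0)
        synth = Xb[72:]
        minority = X[y == 1]
        assert (synth >= minority.min(axis=0) - 1e-12).all()
        assert (synth <= minority.max(axis=0) + 1e-12).all()

    def test_majority_points_never_altered(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(size=(40, 2)), rng.normal(size=(10, 2))])
        y = np.array([0] * 40 + [1] * 10)
        Xb, _ = clf.smote_oversample(X, y, seed=5)
        np.testing.assert_array_equal(Xb[:50], X)

    def test_balanced_input_returned_unchanged(self):
        X = np.arange(20.0).reshape(10, 2)
        y = np.array([0] * 5 + [1] * 5)
        Xb, yb = clf.smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_singleton_class_is_error(self):
        X = np.zeros((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="single member"):
            clf.smote_oversample(X, y)


class TestTrainPredict:
    @pytest.mark.parametrize("algorithm", ["random_forest", "linear_svm",
                                           "logistic_regression",
                                           "gradient_boosting"])
    def test_separable_two_class_toy_is_learned(self, algorithm):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (30, 4)), rng.normal(3, 0.3, (30, 4))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        model = clf.train(clf.ClassifierSpec(algorithm, "binary", seed=0), X, y)
        assert (clf.predict(model, X) == y).all()

    @pytest.mark.parametrize("scheme", ["one_vs_one", "one_vs_rest"])
    def test_multiclass_schemes_on_planted_endotype_scores(self, scheme):
        scores, labels = simulate_scores(n_per_endotype=15, seed=5)
        X = scores.to_numpy().T
        model = clf.train(clf.ClassifierSpec("random_forest", scheme, seed=0),
                          X, labels.to_numpy())
        assert (clf.predict(model, X) == labels.to_numpy()).mean() > 0.95

    def test_label_permutation_destroys_signal(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.3, (40, 4)), rng.normal(3, 0.3, (40, 4))])
        y = rng.permutation(np.array([0] * 40 + [1] * 40))
        tr, val = clf.split_train_validation(range(80), y, 0.75, seed=0)
        model = clf.train(clf.ClassifierSpec("random_forest", "binary", seed=0),
                          X[tr], y[list(tr)])
        acc = (clf.predict(model, X[val]) == y[list(val)]).mean()
        assert acc < 0.8  # near the 0.5 majority-class rate, far below signal

    def test_binary_scheme_needs_two_classes(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError, match="2 classes"):
            clf.train(clf.ClassifierSpec("random_forest", "binary"),
                      X, np.array([0, 1, 2, 0, 1, 2]))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["a", "a", "b", "b", "c"])
        rep = clf.evaluate(y, y)
        assert rep.kappa == pytest.approx(1.0)
        assert rep.accuracy == 1.0
        assert (rep.per_class["sensitivity"] == 1.0).all()
        assert (rep.per_class["specificity"] == 1.0).all()

    def test_hand_confusion_matrix_metrics(self):
        # confusion [[8,2],[1,9]]: sens 0.8/0.9; kappa by direct formula
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.array([0] * 8 + [1] * 2 + [0] * 1 + [1] * 9)
        rep = clf.evaluate(y_true, y_pred)
        assert rep.confusion.to_numpy().tolist() == [[8, 2], [1, 9]]
        assert rep.per_class.loc[0, "sensitivity"] == pytest.approx(0.8)
        assert rep.per_class.loc[1, "sensitivity"] == pytest.approx(0.9)
        assert rep.per_class.loc[0, "specificity"] == pytest.approx(0.9)
        po = 17 / 20
        pe = (10 * 9 + 10 * 11) / 400
        assert rep.kappa == pytest.approx((po - pe) / (1 - pe))
        f1_0 = 2 * (8 / 9) * 0.8 / ((8 / 9) + 0.8)
        assert rep.per_class.loc[0, "f1"] == pytest.approx(f1_0)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 4000)
        s = pd.DataFrame({0: rng.uniform(size=4000)})
        s[1] = 1 - s[0]
        rep = clf.evaluate(y, rng.integers(0, 2, 4000), s)
        assert rep.roc[1]["auc"] == pytest.approx(0.5, abs=0.03)

    def test_report_self_consistent_with_confusion(self):
        scores, labels = simulate_scores(n_per_endotype=10, noise_sd=0.3, seed=8)
        rng = np.random.default_rng(9)
        pred = rng.permutation(labels.to_numpy())
        rep = clf.evaluate(labels.to_numpy(), pred)
        cm = rep.confusion.to_numpy()
        assert cm.sum() == len(labels)
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1).to_numpy(),
            pd.Series(labels).value_counts().sort_index().to_numpy())
        assert rep.accuracy == pytest.approx(np.diag(cm).sum() / cm.sum())


class TestCentroidTransfer:
    def test_exact_centroid_point_gets_its_label(self):
        cents = pd.DataFrame([[0.0, 0.0], [5.0, 5.0]], index=["a", "b"])
        out = clf.centroid_transfer(np.array([[5.0, 5.0], [0.1, -0.1]]), cents)
        assert out.tolist() == ["b", "a"]

    def test_transfer_reproduces_kmeans_labels_on_training_points(self):
        from lupus_endotypes.discovery import kmeans
        scores, _ = simulate_scores(n_per_endotype=12, seed=10)
        res = kmeans(scores, 8, n_restarts=50, seed=0)
        transferred = clf.centroid_transfer(scores.to_numpy().T, res.centroids)
        assert (transferred == res.labels.to_numpy()).all()

    def test_tie_goes_to_first_centroid(self):
        cents = pd.DataFrame([[0.0], [2.0]], index=["first", "second"])
        assert clf.centroid_transfer(np.array([[1.0]]), cents)[0] == "first"


class TestAttribution:
    @staticmethod
    def _single_feature_model(seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(200, 4))
        y = (X[:, 2] > 0).astype(int)
        model = clf.train(clf.ClassifierSpec("random_forest", "binary", seed=0),
                          X, y)
        return model, X, y

    def test_single_informative_feature_dominates_all_methods(self):
        model, X, y = self._single_feature_model()
        gini = clf.feature_attribution(model, X, "gini")
        assert gini.idxmax() == "f2" and gini["f2"] > 0.8
        perm = clf.feature_attribution(model, X, "permutation", y=y)
        assert perm.idxmax() == "f2"
        phi = clf.feature_attribution(model, X[:10], "shapley_mc", n_mc=100,
                                      seed=0, background=X[:50])
        mean_abs = phi.abs().mean()
        assert mean_abs.idxmax() == "f2"
        assert mean_abs["f2"] / mean_abs.sum() > 0.7

    def test_duplicated_feature_splits_attribution(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(-1, 1, 300)
        X = np.column_stack([base, base, rng.uniform(-1, 1, 300)])
        y = (base > 0).astype(int)
        model = clf.train(clf.ClassifierSpec("random_forest", "binary", seed=0),
                          X, y, feature_ids=["copy1", "copy2", "noise"])
        gini = clf.feature_attribution(model, X, "gini")
        assert gini["copy1"] + gini["copy2"] > 0.9
        assert gini["copy1"] > 0.1 and gini["copy2"] > 0.1

    def test_shapley_mc_matches_exhaustive_enumeration(self):
        model, X, _ = self._single_feature_model(seed=12)
        background = X[:40]
        x = X[100]
        f = lambda Z: model.estimator.predict_proba(Z)[:, 1]

        def value(subset):
            Z = background.copy()
            for j in subset:
                Z[:, j] = x[j]
            return f(Z).mean()

        exact = np.zeros(4)
        from math import factorial
        for j in range(4):
            others = [k for k in range(4) if k != j]
            for r in range(4):
                for subset in itertools.combinations(others, r):
                    wgt = factorial(r) * factorial(4 - r - 1) / factorial(4)
                    exact[j] += wgt * (value(set(subset) | {j}) - value(subset))
        phi = clf.shapley_mc(model, x[None, :], n_mc=3000, seed=3,
                             background=background).iloc[0].to_numpy()
        assert np.abs(phi - exact).mean() < 0.02

    def test_shapley_additivity_is_exact_by_construction(self):
        model, X, _ = self._single_feature_model(seed=13)
        background = X[:30]
        phi = clf.shapley_mc(model, X[50:53], n_mc=50, seed=1,
                             background=background)
        f = lambda Z: model.estimator.predict_proba(Z)[:, 1]
        baseline = clf.shapley_baseline(model, background)
        np.testing.assert_allclose(phi.sum(axis=1).to_numpy(),
                                   f(X[50:53]) - baseline, atol=1e-10)

    def test_gini_on_non_tree_model_is_error(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(int)
        model = clf.train(clf.ClassifierSpec("linear_svm", "binary", seed=0), X, y)
        with pytest.raises(ValueError, match="tree"):
            clf.feature_attribution(model, X, "gini")
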