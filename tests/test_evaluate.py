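"""Metric identities, ROC/AUC, classifier training, CV and C tuning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import masstex as mt
from masstex.errors import ConfigurationError, DegenerateLabelsError
from masstex.evaluate import SoftmaxClassifier, make_estimator, positive_proba


def _separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2)) + y[:, None] * 6.0
    return X, y


class TestEvaluate:
    def test_hand_built_confusion_counts(self):
        # TP=3, FN=1, TN=4, FP=2 at threshold 0.5
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p = np.array([.9, .8, .7, .2, .1, .2, .3, .4, .6, .7])
        rep = mt.evaluate(p, y)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (3, 1, 4, 2)
        assert rep.sens == pytest.approx(0.75)
        assert rep.spec == pytest.approx(4 / 6)
        assert rep.acc == pytest.approx(7 / 10)
        assert rep.n_correct == 7 and rep.n == 10

    def test_perfect_and_antiperfect_probabilities(self):
        y = np.array([0, 0, 1, 1])
        perfect = mt.evaluate(np.array([0.0, 0.0, 1.0, 1.0]), y)
        assert (perfect.acc, perfect.sens, perfect.spec, perfect.auc) == (1, 1, 1, 1)
        flipped = mt.evaluate(np.array([1.0, 1.0, 0.0, 0.0]), y)
        assert flipped.auc == 0.0

    @given(st.integers(0, 4), st.integers(1, 200))
    def test_auc_matches_rank_statistic(self, hyp_seed, n):
        """Trapezoidal AUC equals the Mann-Whitney probability that a random
        positive outscores a random negative (ties counted half)."""
        rng = np.random.default_rng(hyp_seed * 1000 + n)
        y = rng.integers(0, 2, size=n + 2)
        y[0], y[1] = 0, 1  # both classes present
        p = rng.random(n + 2).round(2)  # ties occur
        rep = mt.evaluate(p, y)
        pos, neg = p[y == 1], p[y == 0]
        diff = pos[:, None] - neg[None, :]
        mw = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg))
        assert rep.auc == pytest.approx(mw, abs=1e-9)

    def test_single_class_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            mt.evaluate(np.array([0.2, 0.8]), np.array([1, 1]))


class TestSoftmaxHead:
    def test_cross_entropy_decreases(self):
        X, y = _separable(seed=1)
        model = SoftmaxClassifier(seed=0).fit(X, y)
        assert model.loss_trace_[-1] < model.loss_trace_[0]

    def test_deterministic_and_learns_separable(self):
        X, y = _separable(seed=2)
        a = SoftmaxClassifier(seed=3, epochs=500, lr=0.1, dropout=0.2).fit(X, y)
        b = SoftmaxClassifier(seed=3, epochs=500, lr=0.1, dropout=0.2).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))
        assert np.mean(a.predict(X) == y) == 1.0


class TestTrainClassifier:
    def test_svm_rbf_separates_separable(self):
        X, y = _separable()
        model = mt.train_classifier(X, y, mt.ClassifierSpec("svm_rbf", seed=0))
        assert np.mean(model.predict(X) == y) == 1.0

    def test_same_spec_same_predictions(self):
        X, y = _separable(seed=4)
        spec = mt.ClassifierSpec("softmax", seed=9)
        p1 = positive_proba(mt.train_classifier(X, y, spec), X)
        p2 = positive_proba(mt.train_classifier(X, y, spec), X)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("kind", ["svm_linear", "knn", "gradient_boosting"])
    def test_comparison_classifiers_fit_and_predict(self, kind):
        X, y = _separable(seed=5)
        model = mt.train_classifier(X, y, mt.ClassifierSpec(kind, seed=0))
        assert np.mean(model.predict(X) == y) >= 0.9

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            mt.train_classifier(np.zeros((4, 2)), np.zeros(4),
                                mt.ClassifierSpec("svm_rbf"))


class TestCrossValidate:
    def test_stratified_fold_sizes(self):
        X, y = _separable(n=100, seed=6)
        cv = mt.cross_validate(X, y, mt.ClassifierSpec("knn", seed=0), folds=5, seed=0)
        for k in range(5):
            te = cv.fold_assignment == k
            assert te.sum() == 20
            assert y[te].sum() == 10  # 10 per class

    def test_mean_equals_unweighted_fold_mean(self):
        X, y = _separable(n=60, seed=7)
        cv = mt.cross_validate(X, y, mt.ClassifierSpec("svm_rbf", seed=0), 5, 0)
        assert cv.mean_acc == pytest.approx(np.mean([f.acc for f in cv.folds]),
                                            abs=1e-12)

    def test_fold_assignment_deterministic(self):
        X, y = _separable(n=40, seed=8)
        a = mt.cross_validate(X, y, mt.ClassifierSpec("knn"), 4, seed=11)
        b = mt.cross_validate(X, y, mt.ClassifierSpec("knn"), 4, seed=11)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_group_aware_folds_keep_groups_together(self):
        X, y = _separable(n=80, seed=9)
        groups = np.repeat(np.arange(20), 4)  # 4 augmented copies per source
        cv = mt.cross_validate(X, y, mt.ClassifierSpec("knn"), folds=4,
                               seed=0, groups=groups)
        for g in np.unique(groups):
            assert len(np.unique(cv.fold_assignment[groups == g])) == 1


class TestTuneSvmC:
    def test_single_point_grid_returned(self):
        X, y = _separable(seed=10)
        c, _ = mt.tune_svm_c(X[:30], y[:30], X[30:], y[30:], [2.0])
        assert c == 2.0

    def test_tie_breaks_to_smallest_c(self):
        X, y = _separable(seed=11)
        c, accs = mt.tune_svm_c(X[:30], y[:30], X[30:], y[30:],
                                [100.0, 0.1, 1.0, 10.0])
        perfect = [cc for cc, a in accs.items() if a == max(accs.values())]
        assert c == min(perfect)

    def test_empty_grid_rejected(self):
        X, y = _separable()
        with pytest.raises(ConfigurationError):
            mt.tune_svm_c(X, y, X, y, [])
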