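"""Classifiers, folds, metrics and leakage-free cross-validation."""

import numpy as np
import pandas as pd
import pytest

import glottiswt as g
from glottiswt.classify import SgdHyper, train_sgd_linear
from glottiswt.errors import ConfigError


class TestSgdLinear:
    def test_separable_1d_set_learned(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        model = train_sgd_linear(X, y, SgdHyper(epochs=100, seed=0))
        np.testing.assert_array_equal(model.predict(X), y)

    def test_single_epoch_matches_manual_hinge_replay(self):
        # replays the per-sample update by hand: a satisfied margin
        # (t(v.s - k) >= 1) contributes no hinge gradient, only L2 decay
        X2 = np.array([[5.0], [-5.0]])
        y2 = np.array([1, -1])
        m = train_sgd_linear(X2, y2, SgdHyper(eta0=0.1, lam=0.0, epochs=1, seed=0))
        # with lam=0 a sample whose margin is already satisfied must leave
        # (v, k) completely unchanged -- asserted implicitly by the replay
        # replay by hand with the same shuffle order
        for ci, cls in enumerate(m.classes):
            t = np.where(y2 == cls, 1.0, -1.0)
            rng = np.random.default_rng(0 + ci)
            v, k, step = np.zeros(1), 0.0, 0
            for i in rng.permutation(2):
                step += 1
                eta = 0.1 / (1.0 + 0.1 * 0.0 * step)
                if t[i] * (v @ X2[i] - k) < 1.0:
                    v = v + eta * t[i] * X2[i]
                    k = k - eta * t[i]
            np.testing.assert_allclose(m.weights[ci], v)
            np.testing.assert_allclose(m.bias[ci], k)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.array([0, 1] * 15)
        a = train_sgd_linear(X, y, SgdHyper(seed=5))
        b = train_sgd_linear(X, y, SgdHyper(seed=5))
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.bias, b.bias)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            train_sgd_linear(np.ones((3, 2)), np.zeros(3))

    def test_multiclass_one_vs_rest(self, rng):
        centers = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        X = np.vstack([rng.normal(c, 0.3, (20, 2)) for c in centers])
        y = np.repeat([0, 1, 2], 20)
        model = train_sgd_linear(X, y, SgdHyper(epochs=50, seed=1))
        assert np.mean(model.predict(X) == y) == 1.0


class TestSvmRbf:
    def test_xor_pattern_separated(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([0, 0, 1, 1])
        model = g.train_svm_rbf(X, y, gamma=2.0)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_agrees_with_linear_svm_on_separable_data(self, rng):
        X = np.vstack([rng.normal(-2, 0.4, (20, 2)), rng.normal(2, 0.4, (20, 2))])
        y = np.array([-1] * 20 + [1] * 20)
        rbf = g.train_svm_rbf(X, y, c=100.0)
        lin = train_sgd_linear(X, y, SgdHyper(epochs=100, seed=0))
        np.testing.assert_array_equal(rbf.predict(X), lin.predict(X))

    def test_non_support_points_do_not_move_decision(self, rng):
        X = np.vstack([rng.normal(-3, 0.2, (5, 2)), rng.normal(3, 0.2, (5, 2))])
        y = np.array([0] * 5 + [1] * 5)
        model = g.train_svm_rbf(X, y, c=1.0, gamma=0.5)
        sv = set(model.support_)
        non_sv = [i for i in range(10) if i not in sv]
        if not non_sv:
            pytest.skip("all points are support vectors for this draw")
        keep = [i for i in range(10) if i != non_sv[0]]
        refit = g.train_svm_rbf(X[keep], y[keep], c=1.0, gamma=0.5)
        grid = rng.uniform(-4, 4, (50, 2))
        np.testing.assert_allclose(
            model.decision_function(grid), refit.decision_function(grid), atol=1e-6
        )


class TestStratifiedFolds:
    def test_balanced_divisible_case(self):
        labels = np.array([0] * 50 + [1] * 50)
        folds = g.stratified_folds(labels, k=10, seed=0)
        for f in range(10):
            sel = labels[folds == f]
            assert (sel == 0).sum() == 5 and (sel == 1).sum() == 5

    def test_remainder_spread_by_at_most_one(self):
        labels = np.array([1] * 23 + [0] * 77)
        folds = g.stratified_folds(labels, k=10, seed=3)
        pos_counts = [(labels[folds == f] == 1).sum() for f in range(10)]
        assert set(pos_counts) <= {2, 3}

    def test_deterministic_partition(self):
        labels = np.array([0, 1] * 30)
        a = g.stratified_folds(labels, 10, seed=9)
        b = g.stratified_folds(labels, 10, seed=9)
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= 0)

    def test_small_class_rejected_by_name(self):
        labels = np.array(["rare"] * 3 + ["common"] * 30)
        with pytest.raises(ConfigError, match="rare"):
            g.stratified_folds(labels, k=10, seed=0)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        rep = g.evaluate_metrics(y, y, scores=np.array([-1.0, -2, 1, 2]))
        assert rep.ca_pct == 100.0
        assert rep.f1 == 1.0
        assert rep.auc == 1.0

    def test_confusion_example(self):
        # TP=2, FP=1, FN=1, TN=2 (positive class '1')
        y_true = np.array([1, 1, 1, 0, 0, 0])
        y_pred = np.array([1, 1, 0, 1, 0, 0])
        rep = g.evaluate_metrics(y_true, y_pred)
        assert rep.ca_pct == pytest.approx(100 * 4 / 6)
        assert rep.ppv_pct == pytest.approx(100 * 4 / 6)
        assert rep.recall_pct == pytest.approx(100 * 4 / 6)
        assert rep.f1 == pytest.approx(4 / 6)

    def test_auc_perfect_and_reversed_ranking(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        assert g.evaluate_metrics(labels, labels, scores).auc == 1.0
        assert g.evaluate_metrics(1 - labels, 1 - labels, scores).auc == 0.0

    def test_auc_equals_brute_force_pair_count(self, rng):
        # oracle: concordant pairs / total pairs (ties count half)
        labels = rng.integers(0, 2, 40)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        scores = rng.standard_normal(40)
        pos, neg = scores[labels == 1], scores[labels == 0]
        pairs = [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
        brute = np.mean(pairs)
        rep = g.evaluate_metrics(labels, labels, scores)
        assert rep.auc == pytest.approx(brute, abs=1e-12)

    def test_permutation_invariance(self, rng):
        y_true = rng.integers(0, 2, 30)
        y_pred = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        a = g.evaluate_metrics(y_true, y_pred)
        b = g.evaluate_metrics(y_true[perm], y_pred[perm])
        assert (a.ca_pct, a.ppv_pct, a.recall_pct) == (b.ca_pct, b.ppv_pct, b.recall_pct)


class TestCrossValidate:
    @staticmethod
    def _toy_table(rng, n=60):
        labels = np.array(["a", "b"] * (n // 2))
        signal = (labels == "b").astype(float)
        table = pd.DataFrame(
            {
                "good": signal * 3 + rng.normal(0, 0.3, n),
                "noise": rng.standard_normal(n),
            }
        )
        return table, labels

    def test_separable_toy_problem(self, rng):
        table, labels = self._toy_table(rng)
        rep = g.cross_validate(table, labels, g.ClassifierSpec("sgd"), k=5, seed=2)
        assert rep.ca_pct >= 95.0

    def test_k_must_be_at_least_two(self, rng):
        table, labels = self._toy_table(rng)
        with pytest.raises(ConfigError):
            g.cross_validate(table, labels, g.ClassifierSpec("sgd"), k=1, seed=0)

    def test_scaler_fitted_per_fold_without_leakage(self, rng):
        # sentinel oracle: an extreme value placed in one sample changes the
        # cross-validated predictions ONLY through folds where it is part of
        # the training split; when it sits in the test fold, the training
        # scaler (and so every other test sample's scaling) is untouched
        table, labels = self._toy_table(rng)
        folds = g.stratified_folds(labels, 5, seed=2)
        sentinel_fold = 0
        victim = np.flatnonzero(folds == sentinel_fold)[0]
        spoiled = table.copy()
        spoiled.loc[victim, "noise"] = 1e6

        from glottiswt.features import MinMaxScaler

        tr = np.flatnonzero(folds != sentinel_fold)
        scaler = MinMaxScaler().fit(spoiled.iloc[tr][["good", "noise"]])
        assert scaler.max_["noise"] < 1e5  # sentinel never leaks into this fit
        clean_scaler = MinMaxScaler().fit(table.iloc[tr][["good", "noise"]])
        assert scaler.max_["noise"] == clean_scaler.max_["noise"]

    def test_permutation_null_near_chance(self, rng):
        table, labels = self._toy_table(rng, n=100)
        shuffled = rng.permutation(labels)
        rep = g.cross_validate(table, shuffled, g.ClassifierSpec("sgd"), k=10, seed=4)
        assert 30.0 <= rep.ca_pct <= 70.0
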