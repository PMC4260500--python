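"""SVM training, cross-validation, cross-task transfer and permutation
significance, including the exhaustive-enumeration oracle."""

import itertools

import numpy as np
import pytest
from sklearn.svm import SVC

from wmlbci.calibration import zscore_apply, zscore_fit
from wmlbci.classify import (cross_task_evaluate, crossval_10fold,
                             permutation_test, report, report_text, train_svm_rbf)
from wmlbci.features import FeatureMatrix

from conftest import make_clusters

SMALL_C = (1.0, 10.0)
SMALL_G = (0.01, 0.1)


class TestTrainSvm:
    def test_separable_clouds_reach_full_training_accuracy(self):
        X, y = make_clusters(sep=8.0)
        Xz = zscore_apply(X, zscore_fit(X))
        model = train_svm_rbf(Xz, y, cv_seed=0, c_grid=SMALL_C, gamma_grid=SMALL_G)
        _, yi = np.unique(y, return_inverse=True)
        assert (model.predict(Xz) == yi).mean() == 1.0

    def test_deterministic_hyperparameters(self):
        X, y = make_clusters(sep=2.0, seed=3)
        m1 = train_svm_rbf(X, y, cv_seed=5, c_grid=SMALL_C, gamma_grid=SMALL_G)
        m2 = train_svm_rbf(X, y, cv_seed=5, c_grid=SMALL_C, gamma_grid=SMALL_G)
        assert (m1.C, m1.gamma) == (m2.C, m2.gamma)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            train_svm_rbf(X, np.array(["a"] * 10))

    def test_inner_cv_near_chance_under_label_permutation(self):
        """Monte-Carlo null: with labels shuffled relative to the features,
        the inner-CV accuracy (at a fixed hyperparameter) averages ~50%."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((24, 6))
        y = np.array(["a", "b"] * 12)
        accs = []
        for _ in range(100):
            perm = rng.permutation(y)
            m = train_svm_rbf(X, perm, cv_seed=1, c_grid=(1.0,), gamma_grid=(0.05,))
            accs.append(m.inner_cv_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)


class TestCrossval:
    def test_separable_features_classify_nearly_perfectly(self):
        X, y = make_clusters(n_per_class=20, sep=8.0, seed=1)
        acc = crossval_10fold(X, y, seed=0, c_grid=SMALL_C, gamma_grid=SMALL_G)
        assert acc >= 0.95

    def test_label_shuffle_is_at_chance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 5))
        y = np.array(["a", "b"] * 20)
        accs = [crossval_10fold(X, rng.permutation(y), seed=s,
                                c_grid=(1.0,), gamma_grid=(0.05,))
                for s in range(20)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_fold_count_reduced_for_small_classes(self):
        X, y = make_clusters(n_per_class=5, sep=8.0, seed=2)
        acc = crossval_10fold(X, y, seed=0, c_grid=SMALL_C, gamma_grid=SMALL_G,
                              n_folds=10)
        assert acc >= 0.9

    def test_too_few_trials_rejected(self):
        X = np.random.default_rng(0).standard_normal((3, 2))
        with pytest.raises(ValueError):
            crossval_10fold(X, np.array(["a", "a", "b"]))


class TestPermutationTest:
    def _toy(self, n=8, seed=0):
        X, y = make_clusters(n_per_class=n // 2, n_features=3, sep=5.0, seed=seed)
        return X, y

    def test_add_one_convention_lower_bound(self):
        X, y = self._toy()
        p = permutation_test(X, y, X, np.unique(y, return_inverse=True)[1],
                             C=1.0, gamma=0.1, observed_accuracy=2.0, B=19, seed=0)
        assert p == pytest.approx(1.0 / 20.0)

    def test_worst_case_p_is_one(self):
        X, y = self._toy()
        p = permutation_test(X, y, X, np.unique(y, return_inverse=True)[1],
                             C=1.0, gamma=0.1, observed_accuracy=-1.0, B=19, seed=0)
        assert p == 1.0

    def test_invalid_b_rejected(self):
        X, y = self._toy()
        with pytest.raises(ValueError):
            permutation_test(X, y, X, np.zeros(len(y)), 1.0, 0.1, 0.5, B=0)

    def test_matches_exhaustive_enumeration_on_small_set(self):
        """Exhaustive mode equals a brute-force enumeration over all distinct
        label arrangements; Monte-Carlo approximates it."""
        rng = np.random.default_rng(4)
        Xtr = rng.standard_normal((8, 3))
        ytr = np.array(["a"] * 4 + ["b"] * 4)
        Xte = rng.standard_normal((10, 3))
        yte = np.array([0, 1] * 5)
        C, gamma = 1.0, 0.2
        svc = SVC(C=C, gamma=gamma, kernel="rbf").fit(Xtr, np.unique(ytr, return_inverse=True)[1])
        obs = float((svc.predict(Xte) == yte).mean())

        # independent oracle: enumerate positive-class positions directly
        ge = total = 0
        for pos in itertools.combinations(range(8), 4):
            labels = np.zeros(8, dtype=int)
            labels[list(pos)] = 1
            acc = float((SVC(C=C, gamma=gamma, kernel="rbf")
                         .fit(Xtr, labels).predict(Xte) == yte).mean())
            ge += acc >= obs - 1e-12
            total += 1
        oracle_p = ge / total

        p_ex = permutation_test(Xtr, ytr, Xte, yte, C, gamma, obs, exhaustive=True)
        assert p_ex == pytest.approx(oracle_p, abs=1e-12)
        p_mc = permutation_test(Xtr, ytr, Xte, yte, C, gamma, obs, B=400, seed=1)
        assert p_mc == pytest.approx(oracle_p, abs=0.1)


class TestCrossTaskEvaluate:
    def _fm(self, X, y):
        return FeatureMatrix(X, [f"f{i}" for i in range(X.shape[1])], np.asarray(y))

    def test_transfers_separable_structure(self):
        Xtr, ytr = make_clusters(n_per_class=15, sep=8.0, seed=0)
        Xte, yte = make_clusters(n_per_class=10, sep=8.0, seed=1)
        ev = cross_task_evaluate(self._fm(Xtr, ytr), {"wp": self._fm(Xte, yte)},
                                 seed=0, B=199, c_grid=SMALL_C, gamma_grid=SMALL_G)
        r = ev.results[0]
        assert r.accuracy >= 0.95 and r.p_value <= 0.1

    def test_feature_name_mismatch_rejected(self):
        Xtr, ytr = make_clusters(seed=0)
        test = FeatureMatrix(Xtr, [f"g{i}" for i in range(Xtr.shape[1])], ytr)
        with pytest.raises(ValueError):
            cross_task_evaluate(self._fm(Xtr, ytr), {"wp": test}, B=5)

    def test_no_leakage_from_test_trials(self):
        """Removing a test trial must not change scaling statistics or the
        chosen hyperparameters (train-only fitting)."""
        Xtr, ytr = make_clusters(n_per_class=12, sep=3.0, seed=5)
        Xte, yte = make_clusters(n_per_class=8, sep=3.0, seed=6)
        full = cross_task_evaluate(self._fm(Xtr, ytr),
                                   {"wp": self._fm(Xte, yte)}, seed=2, B=9,
                                   c_grid=SMALL_C, gamma_grid=SMALL_G)
        drop = cross_task_evaluate(self._fm(Xtr, ytr),
                                   {"wp": self._fm(Xte[:-1], yte[:-1])}, seed=2, B=9,
                                   c_grid=SMALL_C, gamma_grid=SMALL_G)
        assert (full.model.C, full.model.gamma) == (drop.model.C, drop.model.gamma)
        assert np.allclose(full.model.stats.mean, drop.model.stats.mean)
        assert np.allclose(full.model.stats.sd, drop.model.stats.sd)


class TestReport:
    def _results(self, n_subjects=16):
        from wmlbci.classify import TaskResult

        out = []
        rng = np.random.default_rng(0)
        for i in range(n_subjects):
            for task in ("subtraction", "fraction"):
                out.append(TaskResult(f"s{i}", task, float(rng.uniform(0.5, 1.0)),
                                      float(rng.uniform(0.001, 1.0)), 16))
        return out

    def test_sixteen_subjects_two_tasks_give_32_cells(self):
        summary = report(self._results())
        assert summary["n_cells"] == 32
        assert 0.5 <= summary["mean_accuracy"] <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            report([])

    def test_text_rendering_deterministic(self):
        res = self._results(4)
        assert report_text(report(res)) == report_text(report(res))
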