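"""SVM-RBF training and evaluation: within-task cross-validation and
cross-task transfer with permutation significance.

Hyperparameters (C, gamma) come from an inner grid search on training data
only; z-scoring statistics are likewise fit inside each training split, so
no information leaks from held-out or test trials.  Significance of a
cross-task result is assessed by refitting under uniformly shuffled
training labels and comparing accuracies with the add-one convention
p = (1 + #{permuted >= observed}) / (B + 1).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .calibration import CalibrationStats, zscore_apply, zscore_fit
from .features import FeatureMatrix

#: default hyperparameter grids (coarse log-2)
C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))
GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))


@dataclass
class ClassifierModel:
    """Fitted RBF-SVM with its chosen hyperparameters and provenance."""

    svc: SVC
    C: float
    gamma: float
    classes: np.ndarray
    inner_cv_accuracy: float
    n_train: int
    stats: CalibrationStats | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(X)


def _encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    return classes, y


def _grid_search(
    X: np.ndarray, y: np.ndarray, seed: int,
    c_grid: tuple[float, ...], gamma_grid: tuple[float, ...], inner_folds: int,
) -> tuple[float, float, float]:
    """Stratified inner CV over the (C, gamma) grid; ties keep the first
    grid entry (deterministic)."""
    min_class = np.bincount(y).min()
    folds = int(min(inner_folds, min_class))
    if folds < 2:
        raise ValueError("need at least 2 trials per class for the inner search")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    folds_data = []
    for tr, va in skf.split(X, y):
        stats = zscore_fit(X[tr])
        folds_data.append((zscore_apply(X[tr], stats), y[tr],
                           zscore_apply(X[va], stats), y[va]))
    n_total = sum(len(yva) for _, _, _, yva in folds_data)
    cells = list(itertools.product(range(len(c_grid)), range(len(gamma_grid))))
    # ties prefer moderate hyperparameters (closest to the grid centre):
    # featureless data then gets a non-degenerate kernel instead of the
    # smoothest corner, which would predict a single class for every input
    centre = ((len(c_grid) - 1) / 2.0, (len(gamma_grid) - 1) / 2.0)
    cells.sort(key=lambda ij: (abs(ij[0] - centre[0]) + abs(ij[1] - centre[1]), ij))
    best = (-1.0, None, None)
    for i, j in cells:
        C, gamma = c_grid[i], gamma_grid[j]
        correct = 0
        for Xtr, ytr, Xva, yva in folds_data:
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(Xtr, ytr)
            correct += int((clf.predict(Xva) == yva).sum())
        acc = correct / n_total
        if acc > best[0]:
            best = (acc, C, gamma)
    return best[1], best[2], best[0]


def train_svm_rbf(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    cv_seed: int = 0,
    c_grid: tuple[float, ...] = C_GRID,
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
    inner_folds: int = 3,
) -> ClassifierModel:
    """Grid-searched RBF-SVM refit on all training rows.

    Expects z-scored features (the caller owns the scaling statistics so the
    same transform can be applied to test data).
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = features.labels if labels is None else labels
    else:
        X = np.asarray(features, dtype=float)
    classes, y = _encode(labels)
    if len(classes) < 2:
        raise ValueError("training data holds a single class")
    if np.bincount(y).min() < 2:
        raise ValueError("need at least 2 trials per class")
    C, gamma, inner_acc = _grid_search(X, y, cv_seed, c_grid, gamma_grid, inner_folds)
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(X, y)
    return ClassifierModel(svc, C, gamma, classes, inner_acc, len(y))


def crossval_10fold(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 10,
    c_grid: tuple[float, ...] = C_GRID,
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
    inner_folds: int = 3,
) -> float:
    """Stratified k-fold CV accuracy with scaling and hyperparameter search
    refit inside every training fold (leakage-free)."""
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = features.labels if labels is None else labels
    else:
        X = np.asarray(features, dtype=float)
    classes, y = _encode(labels)
    if len(classes) < 2 or np.bincount(y).min() < 2:
        raise ValueError("need at least 2 trials per class")
    folds = int(min(n_folds, np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        stats = zscore_fit(X[tr])
        Xtr = zscore_apply(X[tr], stats)
        model = train_svm_rbf(Xtr, y[tr], cv_seed=seed, c_grid=c_grid,
                              gamma_grid=gamma_grid, inner_folds=inner_folds)
        correct += int((model.predict(zscore_apply(X[te], stats)) == y[te]).sum())
    return correct / len(y)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

def _fit_fixed(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> SVC:
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(X, y)
    return svc


def permutation_test(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    C: float,
    gamma: float,
    observed_accuracy: float,
    B: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> float:
    """p-value for a cross-task accuracy by refitting under shuffled
    training labels at fixed (C, gamma).

    Monte-Carlo mode draws ``B`` uniform shuffles and applies the add-one
    convention p = (1 + #{perm >= obs}) / (B + 1).  Exhaustive mode
    enumerates every distinct label arrangement (feasible for small sets)
    and returns #{perm >= obs} / n_arrangements, the identity arrangement
    included.
    """
    if not exhaustive and B < 1:
        raise ValueError("B must be >= 1")
    # work in encoded label space so train predictions compare to test_y
    classes, train_y = np.unique(np.asarray(train_y), return_inverse=True)
    test_y = np.asarray(test_y)
    if exhaustive:
        n = len(train_y)
        if len(classes) != 2:
            raise ValueError("exhaustive mode expects two classes")
        n1 = int((train_y == 1).sum())
        ge = 0
        total = 0
        for pos in itertools.combinations(range(n), n1):
            perm = np.zeros(n, dtype=int)
            perm[list(pos)] = 1
            svc = _fit_fixed(train_X, perm, C, gamma)
            acc = float((svc.predict(test_X) == test_y).mean())
            ge += acc >= observed_accuracy - 1e-12
            total += 1
        return ge / total
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(B):
        perm = rng.permutation(train_y)
        svc = _fit_fixed(train_X, perm, C, gamma)
        acc = float((svc.predict(test_X) == test_y).mean())
        ge += acc >= observed_accuracy - 1e-12
    return (1 + ge) / (B + 1)


# ---------------------------------------------------------------------------
# cross-task evaluation
# ---------------------------------------------------------------------------

@dataclass
class TaskResult:
    subject: str
    task: str
    accuracy: float
    p_value: float
    n_test: int


@dataclass
class EvaluationResult:
    results: list[TaskResult]
    model: ClassifierModel | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.results]))

    def significant(self, alpha: float = 0.05) -> int:
        return sum(r.p_value <= alpha for r in self.results)


def cross_task_evaluate(
    train: FeatureMatrix,
    test_sets: dict[str, FeatureMatrix],
    seed: int = 0,
    B: int = 1000,
    c_grid: tuple[float, ...] = C_GRID,
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
    inner_folds: int = 3,
    subject: str = "",
    research_permutations: bool = True,
) -> EvaluationResult:
    """Train one model on the pooled working-memory trials and evaluate it
    separately on each learning task, per-trial, with permutation p-values.

    Scaling statistics and hyperparameters come from the training set only;
    permutation refits share one stream of shuffled label sets, each
    evaluated on every test task.  By default every permutation re-runs the
    full hyperparameter search (``research_permutations``): the permuted
    statistic then goes through exactly the pipeline the observed one did,
    which keeps the test calibrated — with hyperparameters frozen at the
    observed optimum the test is markedly conservative, because tuning on
    the true labels is an asymmetry the permutations never see.
    """
    for name, fm in test_sets.items():
        if fm.feature_names != train.feature_names:
            raise ValueError(f"feature-name mismatch between train and test {name!r}")
    stats = zscore_fit(train)
    Xtr = zscore_apply(train, stats).values
    classes, y = _encode(train.labels)
    model = train_svm_rbf(Xtr, y, cv_seed=seed, c_grid=c_grid,
                          gamma_grid=gamma_grid, inner_folds=inner_folds)
    model.stats = stats

    prepared = {}
    for name, fm in test_sets.items():
        Xte = zscore_apply(fm, stats).values
        yte = np.searchsorted(classes, np.asarray(fm.labels))
        acc = float((model.predict(Xte) == yte).mean())
        prepared[name] = (Xte, yte, acc)

    rng = np.random.default_rng(seed)
    ge = {name: 0 for name in prepared}
    for _ in range(B):
        perm = rng.permutation(y)
        if len(np.unique(perm)) < 2:
            continue
        if research_permutations:
            Cp, gp, _ = _grid_search(Xtr, perm, seed, c_grid, gamma_grid, inner_folds)
            svc = _fit_fixed(Xtr, perm, Cp, gp)
        else:
            svc = _fit_fixed(Xtr, perm, model.C, model.gamma)
        for name, (Xte, yte, acc) in prepared.items():
            pacc = float((svc.predict(Xte) == yte).mean())
            ge[name] += pacc >= acc - 1e-12
    results = [
        TaskResult(subject, name, acc, (1 + ge[name]) / (B + 1), len(yte))
        for name, (Xte, yte, acc) in prepared.items()
    ]
    return EvaluationResult(results, model, {"C": model.C, "gamma": model.gamma,
                                             "n_train": model.n_train})


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(results: list[TaskResult], alpha: float = 0.05, meta: dict | None = None) -> dict:
    """Cohort summary: per-cell table, mean accuracy, significant count."""
    if not results:
        raise ValueError("empty results")
    table = [
        {"subject": r.subject, "task": r.task, "accuracy": round(r.accuracy, 4),
         "p_value": round(r.p_value, 4), "n_test": r.n_test,
         "significant": bool(r.p_value <= alpha)}
        for r in results
    ]
    summary = {
        "n_cells": len(results),
        "mean_accuracy": round(float(np.mean([r.accuracy for r in results])), 4),
        "n_significant": int(sum(r.p_value <= alpha for r in results)),
        "alpha": alpha,
        "table": table,
    }
    if meta:
        summary["meta"] = meta
    return summary


def report_text(summary: dict) -> str:
    lines = [
        f"{'subject':<12}{'task':<14}{'acc':>7}{'p':>9}{'n':>5}  sig",
        "-" * 52,
    ]
    for row in summary["table"]:
        lines.append(
            f"{row['subject']:<12}{row['task']:<14}{row['accuracy']:>7.3f}"
            f"{row['p_value']:>9.4f}{row['n_test']:>5}  {'*' if row['significant'] else ''}"
        )
    lines.append("-" * 52)
    lines.append(
        f"mean accuracy {summary['mean_accuracy']:.3f}; "
        f"{summary['n_significant']}/{summary['n_cells']} significant at "
        f"alpha={summary['alpha']}"
    )
    return "\n".join(lines)


def report_json(summary: dict) -> str:
    return json.dumps(summary, indent=2, sort_keys=True)
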