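"""End-to-end study runners.

``run_study1_subject`` reproduces the within-task design: alternating
theorem/comic study windows, 15-s epoching, alpha-power features, 10-fold
CV.  ``run_study2_subject`` reproduces the cross-task design: four tasks
with ascending difficulty, EOG regression, per-trial activation/rest
interval pairs, 100 %ERD/ERS features, subjective class labeling with
2-of-3 level selection, an SVM trained on the pooled working-memory tasks
and tested per-trial on each learning task with permutation significance.

The desk-scale configuration (`Study2Config.desk()`) shrinks block sizes,
sampling rate, AR order, grids and permutation count so that cohort-level
Monte-Carlo experiments run in minutes on one CPU; the scientific structure
of the pipeline is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import (assign_classes, personal_cutoff, select_difficulty_levels,
                          zscore_fit)
from .classify import (C_GRID, GAMMA_GRID, EvaluationResult, TaskResult,
                       cross_task_evaluate, crossval_10fold)
from .events import LEARNING_TASKS, WM_TASKS
from .features import FeatureMatrix, build_crosstask_features, build_study1_features
from .forward import ForwardModel
from .preprocess import extract_interval_pairs, regress_out_eog, segment_study_windows
from .schedules import build_study1_schedule, build_study2_session
from .forward import simulate_session
from .workload import RatingModel, WorkloadProfile, trial_rating_lookup

log = logging.getLogger(__name__)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31 - 1)]


# ---------------------------------------------------------------------------
# Study 2
# ---------------------------------------------------------------------------

@dataclass
class Study2Config:
    """All knobs of the cross-task pipeline in one place."""

    forward_model: ForwardModel = field(default_factory=ForwardModel)
    profile: WorkloadProfile = field(default_factory=WorkloadProfile)
    rating_model: RatingModel = field(default_factory=RatingModel)
    nback_trials: int = 48
    rspan_letters: int = 24
    n_problems: int = 10
    ar_order: int = 16
    min_interval_s: float = 0.25
    guard_s: float = 0.125
    balance_min: float = 0.4
    B_permutations: int = 1000
    c_grid: tuple[float, ...] = C_GRID
    gamma_grid: tuple[float, ...] = GAMMA_GRID
    inner_folds: int = 3
    artifacts: bool = True
    research_permutations: bool = True

    @classmethod
    def desk(cls, **overrides) -> "Study2Config":
        """Desk-scale conditions: 128 Hz, 24 n-back trials per level, 16
        letter trials per reading-span level, 10 problems per word-problem
        level, AR order 12, 3x3 hyperparameter grid, 79 permutations."""
        cfg = cls(
            forward_model=ForwardModel(rate=128.0),
            nback_trials=24,
            rspan_letters=16,
            n_problems=10,
            ar_order=12,
            B_permutations=79,
            c_grid=(2.0**-1, 2.0**4, 2.0**9),
            gamma_grid=(2.0**-11, 2.0**-7, 2.0**-3),
        )
        return replace(cfg, **overrides)

    def with_signature(self, k_a: float, k_t: float | None = None) -> "Study2Config":
        k_t = k_a * self.forward_model.k_t / max(self.forward_model.k_a, 1e-12) \
            if k_t is None else k_t
        return replace(self, forward_model=self.forward_model.with_(k_a=k_a, k_t=k_t))


@dataclass
class Study2SubjectResult:
    subject: str
    cutoff: float
    kept_levels: dict[str, tuple[int, int]]
    results: list[TaskResult]
    n_train: int
    train_counts: dict[str, int]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.results]))


def run_study2_subject(
    subject_id: str, seed: int, config: Study2Config | None = None
) -> Study2SubjectResult:
    """Simulate one learner's session and run the full cross-task analysis."""
    cfg = config or Study2Config()
    s_sched, s_sim, s_fit = _child_seeds(seed, 3)
    schedule = build_study2_session(
        subject_id, s_sched, nback_trials=cfg.nback_trials,
        rspan_letters=cfg.rspan_letters, n_problems=cfg.n_problems,
    )
    rec, ratings = simulate_session(
        schedule, cfg.forward_model, cfg.profile, cfg.rating_model,
        seed=s_sim, artifacts=cfg.artifacts,
    )
    rec = regress_out_eog(rec)

    # per-task features with per-trial rating provenance
    lookup = trial_rating_lookup(ratings)["get"]
    matrices: dict[str, FeatureMatrix] = {}
    for task in sorted(WM_TASKS | LEARNING_TASKS):
        pairs = extract_interval_pairs(rec, task, min_duration_s=cfg.min_interval_s,
                                       guard_s=cfg.guard_s)
        fm = build_crosstask_features(rec, pairs, ar_order=cfg.ar_order)
        rts = [lookup(task, p["level"], p["trial_index"]) for p in fm.provenance]
        keep = [i for i, r in enumerate(rts) if r is not None]
        fm = fm.subset(np.asarray(keep))
        for i, p in enumerate(fm.provenance):
            p["rating"] = lookup(task, p["level"], p["trial_index"])
        matrices[task] = fm

    # subjective labeling with 2-of-3 level calibration
    cutoff = personal_cutoff(ratings)
    selection = select_difficulty_levels(ratings, cutoff=cutoff,
                                         balance_min=cfg.balance_min)

    def labeled_subset(task: str) -> FeatureMatrix:
        fm = matrices[task]
        keep = [i for i, p in enumerate(fm.provenance)
                if p["level"] in selection.kept[task]]
        fm = fm.subset(np.asarray(keep))
        labeling = assign_classes([p["rating"] for p in fm.provenance], cutoff)
        return fm.with_labels(labeling.classes)

    train = FeatureMatrix.concat([labeled_subset(t) for t in sorted(WM_TASKS)])
    test_sets = {t: labeled_subset(t) for t in sorted(LEARNING_TASKS)}

    evaluation = cross_task_evaluate(
        train, test_sets, seed=s_fit, B=cfg.B_permutations,
        c_grid=cfg.c_grid, gamma_grid=cfg.gamma_grid,
        inner_folds=cfg.inner_folds, subject=subject_id,
        research_permutations=cfg.research_permutations,
    )
    counts = {c: int((train.labels == c).sum()) for c in np.unique(train.labels)}
    return Study2SubjectResult(subject_id, cutoff, selection.kept,
                               evaluation.results, train.n_trials, counts)


def run_study2_cohort(
    n_subjects: int, seed: int, config: Study2Config | None = None
) -> EvaluationResult:
    """Independent simulated learners; per-subject failures (degenerate
    labelings) are counted and skipped rather than aborting the cohort."""
    cfg = config or Study2Config()
    seeds = _child_seeds(seed, n_subjects)
    results: list[TaskResult] = []
    subjects: list[Study2SubjectResult] = []
    failures = 0
    for i, s in enumerate(seeds):
        try:
            sub = run_study2_subject(f"sub{i:03d}", s, cfg)
        except ValueError as exc:
            failures += 1
            log.warning("subject %d skipped: %s", i, exc)
            continue
        subjects.append(sub)
        results.extend(sub.results)
    if not results:
        raise ValueError("every subject failed")
    return EvaluationResult(results, None,
                            {"n_subjects": len(subjects), "n_failures": failures,
                             "subjects": subjects})


# ---------------------------------------------------------------------------
# Study 1
# ---------------------------------------------------------------------------

@dataclass
class Study1Config:
    forward_model: ForwardModel = field(default_factory=ForwardModel)
    profile: WorkloadProfile = field(default_factory=WorkloadProfile)
    rating_model: RatingModel = field(default_factory=RatingModel)
    ar_order: int = 16
    artifact_p2p_uv: float = 150.0
    n_folds: int = 10
    c_grid: tuple[float, ...] = C_GRID
    gamma_grid: tuple[float, ...] = GAMMA_GRID
    artifacts: bool = True

    @classmethod
    def desk(cls, **overrides) -> "Study1Config":
        cfg = cls(
            forward_model=ForwardModel(rate=128.0),
            ar_order=12,
            c_grid=tuple(2.0 ** np.arange(-3, 14, 4)),
            gamma_grid=tuple(2.0 ** np.arange(-13, 2, 4)),
        )
        return replace(cfg, **overrides)


@dataclass
class Study1SubjectResult:
    subject: str
    cv_accuracy: float
    n_epochs: dict[str, int]


def run_study1_subject(
    subject_id: str, seed: int, config: Study1Config | None = None
) -> Study1SubjectResult:
    """Simulate one Study-1 learner and return the 10-fold CV accuracy of
    theorem-vs-comic epoch classification on alpha power."""
    cfg = config or Study1Config()
    s_sched, s_sim, s_fit = _child_seeds(seed, 3)
    schedule = build_study1_schedule(subject_id, s_sched)
    rec, _ = simulate_session(schedule, cfg.forward_model, cfg.profile,
                              cfg.rating_model, seed=s_sim, artifacts=cfg.artifacts)
    rec = regress_out_eog(rec)
    epochs = segment_study_windows(rec, artifact_p2p_uv=cfg.artifact_p2p_uv)
    fm = build_study1_features(epochs, rec.rate, rec.channels, ar_order=cfg.ar_order)
    acc = crossval_10fold(fm, seed=s_fit, n_folds=cfg.n_folds,
                          c_grid=cfg.c_grid, gamma_grid=cfg.gamma_grid)
    counts = {c: int((fm.labels == c).sum()) for c in np.unique(fm.labels)}
    return Study1SubjectResult(subject_id, acc, counts)


def run_study1_cohort(
    n_subjects: int, seed: int, config: Study1Config | None = None
) -> list[Study1SubjectResult]:
    cfg = config or Study1Config()
    return [run_study1_subject(f"sub{i:03d}", s, cfg)
            for i, s in enumerate(_child_seeds(seed, n_subjects))]
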