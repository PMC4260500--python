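"""Class definition from subjective ratings, difficulty-level calibration,
and train-statistics z-scoring.

Classes are *subjective*: a personal cutoff (the mean rating over all of a
subject's working-memory task blocks) splits trials of every task into low
vs high experienced load.  Because absolute difficulty differs across tasks,
two of the three levels are retained per task so that all tasks cover a
similar rating range with reasonably balanced classes.  Feature scaling uses
means/standard deviations estimated on training data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import WM_TASKS
from .features import FeatureMatrix
from .workload import RatingRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# personal cutoff and class assignment
# ---------------------------------------------------------------------------

def personal_cutoff(wm_ratings: list[int] | list[RatingRecord]) -> float:
    """Arithmetic mean of all working-memory-task ratings of one subject."""
    if wm_ratings and isinstance(wm_ratings[0], RatingRecord):
        values = [r.rating for r in wm_ratings if r.task in WM_TASKS]
    else:
        values = list(wm_ratings)
    if not values:
        raise ValueError("no working-memory-task ratings")
    return float(np.mean(values))


@dataclass
class ClassLabeling:
    """Low/high class per trial under a fixed personal cutoff."""

    cutoff: float
    classes: np.ndarray          # array of "low"/"high"
    degenerate: bool = False     # all ratings equal to the cutoff

    @property
    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.classes, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


def assign_classes(
    ratings: list[int] | np.ndarray,
    cutoff: float,
    tie: str = "high",
    require_both: bool = True,
) -> ClassLabeling:
    """rating > cutoff -> high, rating < cutoff -> low, ties per ``tie``.

    The same rule applies to working-memory and learning tasks (never
    re-estimated on the test tasks).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if tie not in ("high", "low"):
        raise ValueError("tie must be 'high' or 'low'")
    r = np.asarray(ratings, dtype=float)
    if r.size == 0:
        raise ValueError("no ratings")
    classes = np.where(r > cutoff, "high", np.where(r < cutoff, "low", tie))
    labeling = ClassLabeling(cutoff, classes, degenerate=bool(np.all(r == cutoff)))
    if require_both and len(np.unique(classes)) < 2:
        raise ValueError(
            "one class is empty after assignment; re-select difficulty levels"
        )
    return labeling


# ---------------------------------------------------------------------------
# 2-of-3 difficulty-level selection
# ---------------------------------------------------------------------------

@dataclass
class LevelSelection:
    kept: dict[str, tuple[int, int]]
    dropped: dict[str, int]
    diagnostics: dict = field(default_factory=dict)


def select_difficulty_levels(
    records: list[RatingRecord],
    cutoff: float | None = None,
    balance_min: float = 0.4,
    tie: str = "high",
) -> LevelSelection:
    """Retain two of the three difficulty levels per task.

    Per task, candidate drops are ordered by how far the level's mean rating
    deviates from the cross-task grand mean rating (most deviant first;
    symmetric ties drop the lower level).  The first candidate whose
    retained pair yields a minority-class fraction of at least
    ``balance_min`` under the cutoff rule wins; if none qualifies, a
    diagnostic error is raised.
    """
    if cutoff is None:
        cutoff = personal_cutoff(records)
    by_task: dict[str, dict[int, list[RatingRecord]]] = {}
    for r in records:
        if r.level is None:
            continue
        by_task.setdefault(r.task, {}).setdefault(r.level, []).append(r)

    level_means: dict[tuple[str, int], float] = {}
    for task, levels in by_task.items():
        for level, recs in levels.items():
            level_means[(task, level)] = float(np.mean([r.rating for r in recs]))
    grand_mean = float(np.mean(list(level_means.values())))

    kept: dict[str, tuple[int, int]] = {}
    dropped: dict[str, int] = {}
    diag: dict = {"grand_mean": grand_mean, "level_means": {
        f"{t}:{l}": m for (t, l), m in sorted(level_means.items())}, "cutoff": cutoff}
    for task, levels in sorted(by_task.items()):
        if len(levels) < 3:
            raise ValueError(f"task {task!r} needs three levels, has {sorted(levels)}")
        # most deviant first; ties resolved toward dropping the lower level
        candidates = sorted(
            levels, key=lambda l: (-abs(level_means[(task, l)] - grand_mean), l)
        )
        chosen = None
        for cand in candidates:
            keep = tuple(sorted(l for l in levels if l != cand))
            ratings = [r.rating for l in keep for r in levels[l]
                       for _ in range(r.n_trials)]
            r = np.asarray(ratings, dtype=float)
            cls = np.where(r > cutoff, "high", np.where(r < cutoff, "low", tie))
            counts = {c: int((cls == c).sum()) for c in ("low", "high")}
            frac = min(counts.values()) / max(len(cls), 1)
            diag[f"{task}:drop{cand}"] = {"keep": keep, "counts": counts,
                                          "minority_fraction": round(frac, 3)}
            if frac >= balance_min:
                chosen = cand
                break
        if chosen is None:
            raise ValueError(
                f"no 2-of-3 selection for task {task!r} satisfies the "
                f"balance constraint (>= {balance_min:.0%} minority); "
                f"diagnostics: {diag}"
            )
        dropped[task] = chosen
        kept[task] = tuple(sorted(l for l in levels if l != chosen))
    return LevelSelection(kept, dropped, diag)


# ---------------------------------------------------------------------------
# z-scoring with train-only statistics
# ---------------------------------------------------------------------------

@dataclass
class CalibrationStats:
    """Per-feature mean/sd (population) estimated on training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: list[str] | None = None


def zscore_fit(training: FeatureMatrix | np.ndarray) -> CalibrationStats:
    x = training.values if isinstance(training, FeatureMatrix) else np.asarray(training, float)
    if x.size == 0:
        raise ValueError("empty training matrix")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population (n) convention
    zero = sd == 0
    if np.any(zero):
        log.warning("zscore_fit: %d zero-sd columns; sd replaced by 1", int(zero.sum()))
        sd = np.where(zero, 1.0, sd)
    names = training.feature_names if isinstance(training, FeatureMatrix) else None
    return CalibrationStats(mean, sd, names)


def zscore_apply(matrix: FeatureMatrix | np.ndarray, stats: CalibrationStats):
    """Transform any matrix with training statistics (never refit on test)."""
    if isinstance(matrix, FeatureMatrix):
        if stats.feature_names is not None and matrix.feature_names != stats.feature_names:
            raise ValueError("feature-name mismatch between matrix and stats")
        return FeatureMatrix((matrix.values - stats.mean) / stats.sd,
                             list(matrix.feature_names), matrix.labels,
                             list(matrix.provenance))
    return (np.asarray(matrix, float) - stats.mean) / stats.sd
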