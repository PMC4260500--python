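"""Latent working-memory load, learning decay, and subjective ratings.

The latent load W of a trial lives in [0, 1] and is set by the task and its
difficulty level, decaying exponentially over repeated trials of the same
level as the learner acquires schemata:

    W_trial = floor + (base - floor) * exp(-decay * trial_index_within_level)

Within a trial, W carries that magnitude only during the activation segment
(stimulus processing up to the response); rest segments sit at zero load.
Subjective 7-point ratings are a noisy rounded linear readout of W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import LEARNING_TASKS, STUDY1_TASKS, WM_TASKS, SessionSchedule
from .schedules import TrialAnchors, iter_trials

#: default latent load per (task, difficulty level); Study-1 materials carry a
#: constant load per material type.  Chosen so that the two retained levels of
#: every Study-2 task straddle a typical personal rating cutoff, the first
#: subtraction level is by far the easiest condition, and the third fraction
#: level is the hardest.
DEFAULT_BASE_LOAD: dict[tuple[str, int | None], float] = {
    ("nback", 1): 0.20, ("nback", 2): 0.40, ("nback", 3): 0.78,
    ("reading_span", 1): 0.25, ("reading_span", 2): 0.38, ("reading_span", 3): 0.78,
    ("subtraction", 1): 0.08, ("subtraction", 2): 0.35, ("subtraction", 3): 0.62,
    ("fraction", 1): 0.35, ("fraction", 2): 0.60, ("fraction", 3): 0.88,
    ("study1_theorem", None): 0.75, ("study1_comic", None): 0.25,
}


@dataclass
class WorkloadProfile:
    """Latent-load configuration for a simulated learner."""

    base_load: dict[tuple[str, int | None], float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_LOAD)
    )
    learning_decay_rate: float = 0.02  # per trial within a difficulty level
    floor: float = 0.05
    overload_reversal: bool = False
    reversal_threshold: float = 0.85

    def __post_init__(self) -> None:
        if self.learning_decay_rate < 0:
            raise ValueError("learning_decay_rate must be >= 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if not 0 < self.reversal_threshold <= 1:
            raise ValueError("reversal_threshold must be in (0, 1]")
        self.base_load = {k: float(np.clip(v, 0.0, 1.0)) for k, v in self.base_load.items()}

    def load(self, task_id: str, level: int | None, trial_index_within_level: int) -> float:
        key = (task_id, level)
        if key not in self.base_load:
            raise KeyError(f"no base load configured for task={task_id!r} level={level!r}")
        base = self.base_load[key]
        w = self.floor + (base - self.floor) * np.exp(
            -self.learning_decay_rate * trial_index_within_level
        )
        return float(np.clip(w, 0.0, 1.0))


@dataclass
class TrialLoad:
    """Per-trial latent load with its activation span."""

    anchors: TrialAnchors
    w: float


def simulate_latent_workload(
    schedule: SessionSchedule,
    profile: WorkloadProfile,
    seed: int | None = None,
) -> list[TrialLoad]:
    """Latent load for every analysable trial of the schedule.

    Deterministic given the schedule and profile (the decay model has no
    noise); ``seed`` is accepted for interface symmetry with the generator.
    """
    tasks = sorted({e.task_id for e in schedule.events if e.task_id is not None})
    loads: list[TrialLoad] = []
    for task in tasks:
        counters: dict[int | None, int] = {}
        for tr in iter_trials(schedule, task):
            idx = counters.get(tr.level, 0)
            counters[tr.level] = idx + 1
            loads.append(TrialLoad(tr, profile.load(task, tr.level, idx)))
    return loads


@dataclass
class RatingModel:
    """Monotone link from latent load to the 7-point Likert scale:
    rating = clip(round(1 + 6 W + eps), 1, 7), eps ~ N(0, noise_sd)."""

    noise_sd: float = 0.2

    def rate(self, w: float, rng: np.random.Generator) -> int:
        raw = 1.0 + 6.0 * float(w) + self.noise_sd * rng.standard_normal()
        return int(np.clip(np.rint(raw), 1, 7))


@dataclass
class RatingRecord:
    """One obtained rating: block-level for WM tasks, trial-level otherwise."""

    subject: str
    task: str
    level: int | None
    index: int          # block index for WM tasks, trial index otherwise
    rating: int
    error_rate: float
    n_trials: int = 1   # trials the rating covers (block size for WM tasks)

    def __post_init__(self) -> None:
        if not 1 <= self.rating <= 7:
            raise ValueError("rating must be in 1..7")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0,1]")


def generate_ratings(
    schedule: SessionSchedule,
    loads: list[TrialLoad],
    model: RatingModel,
    rng: np.random.Generator,
) -> list[RatingRecord]:
    """Subjective load ratings coupled to the latent load.

    Working-memory tasks are rated once per block (trials inherit the block
    rating downstream); learning tasks and Study-1 study windows are rated
    per trial/window.
    """
    records: list[RatingRecord] = []
    by_task: dict[str, list[TrialLoad]] = {}
    for tl in loads:
        by_task.setdefault(tl.anchors.task_id, []).append(tl)
    for task, tls in sorted(by_task.items()):
        if task in WM_TASKS:
            by_level: dict[int, list[TrialLoad]] = {}
            for tl in tls:
                by_level.setdefault(tl.anchors.level, []).append(tl)
            for bi, (level, group) in enumerate(sorted(by_level.items())):
                mean_w = float(np.mean([tl.w for tl in group]))
                err = float(np.clip(
                    0.03 + 0.25 * mean_w + 0.03 * rng.standard_normal(), 0.0, 1.0
                ))
                records.append(
                    RatingRecord(schedule.subject_id, task, level, bi,
                                 model.rate(mean_w, rng), err, n_trials=len(group))
                )
        elif task in LEARNING_TASKS or task in STUDY1_TASKS:
            for tl in tls:
                err = float(np.clip(
                    0.03 + 0.25 * tl.w + 0.05 * rng.standard_normal(), 0.0, 1.0
                ))
                records.append(
                    RatingRecord(schedule.subject_id, task, tl.anchors.level,
                                 tl.anchors.trial_index, model.rate(tl.w, rng), err)
                )
    return records


def trial_rating_lookup(records: list[RatingRecord]) -> dict:
    """Map (task, level, trial_index) -> rating, expanding block-level WM
    ratings so that every trial inherits its block's rating."""
    block_rating = {(r.task, r.level): r.rating for r in records if r.task in WM_TASKS}
    trial_rating = {
        (r.task, r.level, r.index): r.rating for r in records if r.task not in WM_TASKS
    }

    def lookup(task: str, level: int | None, trial_index: int) -> int | None:
        if task in WM_TASKS:
            return block_rating.get((task, level))
        return trial_rating.get((task, level, trial_index))

    return {"block": block_rating, "trial": trial_rating, "get": lookup}
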