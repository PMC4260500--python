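"""Session timelines: tasks, trial events, and schedules.

A :class:`SessionSchedule` is the shared container between the paradigm
builders, the synthetic-EEG generator and the preprocessing stage.  It is a
strictly time-sorted stream of :class:`TrialEvent` records plus per-block
:class:`TaskSpec` metadata, and serializes to an events TSV + JSON header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

STUDY1_TASKS = frozenset({"study1_theorem", "study1_comic"})
STUDY2_TASKS = frozenset({"nback", "reading_span", "subtraction", "fraction"})
WM_TASKS = frozenset({"nback", "reading_span"})
LEARNING_TASKS = frozenset({"subtraction", "fraction"})
ALL_TASKS = STUDY1_TASKS | STUDY2_TASKS

EVENT_KINDS = frozenset(
    {"stimulus", "keypress", "fixation", "rating_prompt", "block_start", "block_end"}
)


@dataclass(frozen=True)
class TaskSpec:
    """One task block: identity, difficulty level, and named durations."""

    task_id: str
    difficulty_level: int | None = None
    timing: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task_id not in ALL_TASKS:
            raise ValueError(f"unknown task_id {self.task_id!r}")
        is_study2 = self.task_id in STUDY2_TASKS
        if is_study2 and self.difficulty_level not in (1, 2, 3):
            raise ValueError(
                f"{self.task_id}: difficulty_level must be 1-3, got {self.difficulty_level}"
            )
        if not is_study2 and self.difficulty_level is not None:
            raise ValueError(f"{self.task_id}: difficulty_level not applicable")
        for name, dur in self.timing.items():
            if not dur > 0:
                raise ValueError(f"duration {name}={dur} must be > 0")


@dataclass
class TrialEvent:
    """A single timeline event (stimulus, keypress, fixation, ...)."""

    onset_s: float
    duration_s: float
    kind: str
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def task_id(self) -> str | None:
        return self.payload.get("task_id")

    @property
    def level(self) -> int | None:
        return self.payload.get("level")

    @property
    def trial_index(self) -> int | None:
        return self.payload.get("trial_index")

    @property
    def role(self) -> str | None:
        return self.payload.get("role")


@dataclass
class SessionSchedule:
    """Ordered event stream for one recording session (or a block fragment)."""

    subject_id: str
    events: list[TrialEvent]
    blocks: list[TaskSpec] = field(default_factory=list)
    total_duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset_s, e.kind != "block_start"))
        if self.events:
            last_end = max(e.end_s for e in self.events)
            if self.total_duration_s < last_end:
                self.total_duration_s = last_end

    # -- queries -----------------------------------------------------------
    def events_of_kind(self, kind: str) -> list[TrialEvent]:
        return [e for e in self.events if e.kind == kind]

    def keypress_times(self) -> list[float]:
        return [e.onset_s for e in self.events if e.kind == "keypress"]

    def task_events(self, task_id: str) -> list[TrialEvent]:
        return [e for e in self.events if e.task_id == task_id]

    # -- composition -------------------------------------------------------
    def shifted(self, offset_s: float) -> "SessionSchedule":
        ev = [
            TrialEvent(e.onset_s + offset_s, e.duration_s, e.kind, dict(e.payload))
            for e in self.events
        ]
        return SessionSchedule(self.subject_id, ev, list(self.blocks))

    @staticmethod
    def concatenate(
        subject_id: str,
        fragments: Sequence["SessionSchedule"],
        gap_s: float = 5.0,
    ) -> "SessionSchedule":
        events: list[TrialEvent] = []
        blocks: list[TaskSpec] = []
        t = 0.0
        for frag in fragments:
            shifted = frag.shifted(t)
            events.extend(shifted.events)
            blocks.extend(frag.blocks)
            t = shifted.total_duration_s + gap_s
        return SessionSchedule(subject_id, events, blocks)

    # -- serialization -----------------------------------------------------
    TSV_COLUMNS = ("onset_s", "duration_s", "kind", "task_id", "level", "trial_index", "value")

    def to_files(self, directory: str | Path) -> None:
        """Write ``events.tsv`` and ``session.json`` under *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "events.tsv", "w") as fh:
            fh.write("\t".join(self.TSV_COLUMNS) + "\tpayload_json\n")
            for e in self.events:
                value = e.payload.get("value", e.payload.get("digit", e.payload.get("letter", "")))
                row = [
                    repr(float(e.onset_s)),
                    repr(float(e.duration_s)),
                    e.kind,
                    str(e.task_id or ""),
                    "" if e.level is None else str(e.level),
                    "" if e.trial_index is None else str(e.trial_index),
                    "" if value is None else str(value),
                    json.dumps(e.payload, sort_keys=True),
                ]
                fh.write("\t".join(row) + "\n")
        header = {
            "subject_id": self.subject_id,
            "total_duration_s": self.total_duration_s,
            "blocks": [
                {
                    "task_id": b.task_id,
                    "difficulty_level": b.difficulty_level,
                    "timing": b.timing,
                }
                for b in self.blocks
            ],
        }
        (directory / "session.json").write_text(json.dumps(header, indent=2))

    @staticmethod
    def from_files(directory: str | Path) -> "SessionSchedule":
        directory = Path(directory)
        header = json.loads((directory / "session.json").read_text())
        events = []
        with open(directory / "events.tsv") as fh:
            cols = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                rec = dict(zip(cols, line.rstrip("\n").split("\t")))
                events.append(
                    TrialEvent(
                        float(rec["onset_s"]),
                        float(rec["duration_s"]),
                        rec["kind"],
                        json.loads(rec["payload_json"]),
                    )
                )
        blocks = [
            TaskSpec(b["task_id"], b["difficulty_level"], b.get("timing", {}))
            for b in header.get("blocks", [])
        ]
        sched = SessionSchedule(header["subject_id"], events, blocks)
        sched.total_duration_s = float(header["total_duration_s"])
        return sched


def check_sorted(events: Iterable[TrialEvent]) -> bool:
    onsets = [e.onset_s for e in events]
    return all(a <= b for a, b in zip(onsets, onsets[1:]))
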