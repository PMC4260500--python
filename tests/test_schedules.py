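"""Paradigm-builder contracts: counts, timing grids, alphabets, formulas,
ordering, and the absence of visual-structure confounds across levels."""

import numpy as np
import pytest

from wmlbci.events import SessionSchedule, TaskSpec, check_sorted
from wmlbci.schedules import (NBACK_DIGITS, READING_SPAN_LETTERS,
                              build_nback_block, build_readingspan_block,
                              build_study1_schedule, build_study2_session,
                              build_wordproblem_block, iter_trials)


class TestStudy1Schedule:
    def test_window_counts_per_material(self):
        sched = build_study1_schedule("s1", 0)
        windows = [e for e in sched.events if e.role == "study_window"]
        per_mat = {m: sum(e.task_id == f"study1_{m}" for e in windows)
                   for m in ("theorem", "comic")}
        assert per_mat == {"theorem": 15, "comic": 15}
        assert len(windows) == 30

    def test_alternation_never_repeats_material(self):
        sched = build_study1_schedule("s1", 1)
        windows = [e for e in sched.events if e.role == "study_window"]
        mats = [e.task_id for e in windows]
        assert all(a != b for a, b in zip(mats, mats[1:]))

    def test_each_window_followed_by_question_and_rating(self):
        sched = build_study1_schedule("s1", 2)
        questions = [e for e in sched.events if e.role == "question"]
        ratings = sched.events_of_kind("rating_prompt")
        assert len(questions) == 30 and len(ratings) == 30
        assert all(q.duration_s == 10.0 for q in questions)
        assert all(r.duration_s == 10.0 for r in ratings)

    def test_episode_duration_about_eleven_minutes(self):
        sched = build_study1_schedule("s1", 3)
        # 10 windows x (45 + 10 + 10) s = 650 s per episode
        assert sched.total_duration_s == pytest.approx(3 * 650.0)


class TestNback:
    def test_stimulus_grid_is_exactly_2000_ms(self):
        blk = build_nback_block(2, 48, 0)
        onsets = [e.onset_s for e in blk.events if e.role == "digit"]
        assert len(onsets) == 48
        assert onsets == pytest.approx(list(np.arange(48) * 2.0))

    def test_digit_alphabet_excludes_seven(self):
        blk = build_nback_block(3, 200, 1)
        digits = {e.payload["digit"] for e in blk.events if e.role == "digit"}
        assert 7 not in digits
        assert digits <= set(NBACK_DIGITS)

    @pytest.mark.parametrize("level,n", [(0, 10), (4, 10), (2, 0), (2, 2)])
    def test_invalid_level_or_trial_count_rejected(self, level, n):
        with pytest.raises(ValueError):
            build_nback_block(level, n, 0)

    def test_one_keypress_inside_each_interstimulus_interval(self):
        blk = build_nback_block(1, 30, 2)
        stims = [e for e in blk.events if e.role == "digit"]
        kps = [e for e in blk.events if e.kind == "keypress"]
        assert len(kps) == len(stims)
        for s, k in zip(stims, kps):
            assert s.onset_s < k.onset_s < s.onset_s + 2.0


class TestReadingSpan:
    def test_letter_and_fixation_durations(self):
        blk = build_readingspan_block(4, 3, 0)
        letters = [e for e in blk.events if e.role == "letter"]
        fixes = blk.events_of_kind("fixation")
        assert all(e.duration_s == 1.0 for e in letters)
        assert all(e.duration_s == 0.5 for e in fixes)

    def test_letters_distinct_within_span(self):
        blk = build_readingspan_block(6, 4, 3)
        by_span = {}
        for e in blk.events:
            if e.role == "letter":
                by_span.setdefault(e.payload["span"], []).append(e.payload["letter"])
        for letters in by_span.values():
            assert len(letters) == 6 == len(set(letters))
            assert set(letters) <= set(READING_SPAN_LETTERS)

    @pytest.mark.parametrize("span", [1, 3, 5, 7])
    def test_invalid_span_rejected(self, span):
        with pytest.raises(ValueError):
            build_readingspan_block(span, 3, 0)


class TestWordProblems:
    @pytest.mark.parametrize("task", ["subtraction", "fraction"])
    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_every_problem_has_four_givens_and_formula_answer(self, task, level):
        blk = build_wordproblem_block(task, level, 12, 5)
        problems = [e for e in blk.events if e.role == "problem"]
        facts = [e for e in blk.events if e.role == "fact"]
        assert len(problems) == 12
        for f in facts:
            assert len(f.payload["givens"]) == 4
        for p in problems:
            prm = p.payload["params"]
            if task == "subtraction":
                expected = {1: lambda: prm["a"],
                            2: lambda: prm["a"] - prm["b"],
                            3: lambda: (prm["a"] - prm["b"]) - (prm["c"] - prm["d"]),
                            }[level]()
            else:
                expected = {1: lambda: prm["c"] * prm["a"] / prm["b"],
                            2: lambda: prm["c"] * prm["a"] / prm["b"]
                            + prm["d"] * prm["a"] / prm["b"],
                            3: lambda: prm["c"] * prm["a"] / prm["b"]
                            + prm["d"] * prm["e"] / prm["f"],
                            }[level]()
            assert p.payload["answer"] == pytest.approx(expected)

    def test_no_feedback_events(self):
        blk = build_wordproblem_block("fraction", 2, 8, 1)
        assert not any("feedback" in str(e.payload.get("role", "")) for e in blk.events)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            build_wordproblem_block("subtraction", 4, 5, 0)
        with pytest.raises(ValueError):
            build_wordproblem_block("nback", 1, 5, 0)


class TestSessionComposition:
    def test_levels_non_decreasing_within_each_task(self):
        sched = build_study2_session("s1", 9, nback_trials=8, rspan_letters=6,
                                     n_problems=3)
        for task in ("nback", "reading_span", "subtraction", "fraction"):
            levels = [e.level for e in sched.events
                      if e.task_id == task and e.kind == "stimulus"]
            assert levels == sorted(levels)

    def test_events_strictly_time_sorted(self):
        sched = build_study2_session("s1", 10, nback_trials=8, rspan_letters=6,
                                     n_problems=3)
        assert check_sorted(sched.events)

    def test_visual_event_structure_identical_across_levels(self):
        """Per-trial visual event kinds must not differ between difficulty
        levels of the same task (no perceptual confound of difficulty)."""
        sched = build_study2_session("s1", 11, nback_trials=8, rspan_letters=12,
                                     n_problems=4)
        for task in ("nback", "subtraction", "fraction", "reading_span"):
            per_level = {}
            for lvl in (1, 2, 3):
                trials = {}
                for e in sched.events:
                    if e.task_id == task and e.level == lvl and e.trial_index is not None:
                        trials.setdefault(e.trial_index, []).append(e.kind)
                per_level[lvl] = {tuple(sorted(v)) for v in trials.values()}
            assert per_level[1] == per_level[2] == per_level[3]

    def test_tsv_roundtrip(self, tmp_path):
        sched = build_study2_session("s7", 12, nback_trials=8, rspan_letters=6,
                                     n_problems=3)
        sched.to_files(tmp_path)
        back = SessionSchedule.from_files(tmp_path)
        assert back.subject_id == "s7"
        assert len(back.events) == len(sched.events)
        assert back.total_duration_s == pytest.approx(sched.total_duration_s)
        for a, b in zip(sched.events, back.events):
            assert (a.onset_s, a.duration_s, a.kind) == (b.onset_s, b.duration_s, b.kind)
            assert a.payload == b.payload


class TestTaskSpec:
    def test_level_required_iff_study2(self):
        with pytest.raises(ValueError):
            TaskSpec("nback", None)
        with pytest.raises(ValueError):
            TaskSpec("study1_comic", 2)
        with pytest.raises(ValueError):
            TaskSpec("nback", 2, {"isi_s": -1.0})

    def test_iter_trials_rejects_unknown_task(self):
        sched = build_nback_block(1, 5, 0)
        with pytest.raises(ValueError):
            iter_trials(sched, "sternberg")
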