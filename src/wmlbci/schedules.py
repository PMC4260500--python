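"""Paradigm builders: the alternating learning design and the four
working-memory / word-problem tasks.

Design constraints enforced here:

* difficulty levels appear in non-decreasing (simple-to-complex) order
  within each task;
* the number and kind of visual events per trial is identical across
  difficulty levels of the same task, so difficulty is never confounded
  with the visual event structure;
* simulated reaction times are log-normal (positively skewed, like real
  keypress latencies) and clipped so that every trial retains usable
  activation and rest intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .events import STUDY1_TASKS, STUDY2_TASKS, SessionSchedule, TaskSpec, TrialEvent

NBACK_DIGITS = (1, 2, 3, 4, 5, 6, 8, 9)  # single digits; 7 excluded (two syllables)
READING_SPAN_LETTERS = ("B", "F", "H", "J", "L", "M", "Q", "R", "X")
SPAN_FOR_LEVEL = {1: 2, 2: 4, 3: 6}  # reading-span difficulty -> letters/sentences


@dataclass(frozen=True)
class ReactionTimes:
    """Log-normal keypress latency model (median in seconds)."""

    median_s: float
    sigma: float
    lo_s: float
    hi_s: float

    def draw(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        rt = self.median_s * np.exp(self.sigma * rng.standard_normal(n))
        return np.clip(rt, self.lo_s, self.hi_s)


# per-role latency defaults; clipped so intervals never collapse below the
# minimum analysable duration on the 2-s n-back grid
RT_NBACK = ReactionTimes(0.75, 0.30, 0.45, 1.55)
RT_SENTENCE = ReactionTimes(2.5, 0.30, 1.2, 6.0)
RT_FACT = ReactionTimes(3.0, 0.35, 1.5, 7.0)
RT_PROBLEM = ReactionTimes(4.0, 0.35, 2.0, 9.0)
RT_CHOICE = ReactionTimes(2.5, 0.30, 1.2, 6.0)
RT_QUESTION = ReactionTimes(4.0, 0.35, 1.5, 9.0)


# ---------------------------------------------------------------------------
# Study-1 alternating learning design
# ---------------------------------------------------------------------------

def build_study1_schedule(
    subject_id: str,
    rng_seed: int,
    n_episodes: int = 3,
    windows_per_material: int = 5,
    window_s: float = 45.0,
    question_s: float = 10.0,
    rating_s: float = 10.0,
    start_material: str = "comic",
) -> SessionSchedule:
    """Alternating theorem/comic learning session.

    Each episode holds ``windows_per_material`` 45-s theorem study windows and
    as many comic windows, strictly alternating; every study window is
    followed by a 10-s multiple-choice question and a 10-s load-rating prompt.
    """
    if start_material not in ("comic", "theorem"):
        raise ValueError("start_material must be 'comic' or 'theorem'")
    for name, v in [("window_s", window_s), ("question_s", question_s), ("rating_s", rating_s)]:
        if not v > 0:
            raise ValueError(f"{name} must be > 0")
    rng = np.random.default_rng(rng_seed)
    order = ["comic", "theorem"] if start_material == "comic" else ["theorem", "comic"]
    events: list[TrialEvent] = []
    counters = {"comic": 0, "theorem": 0}
    t = 0.0
    for ep in range(n_episodes):
        events.append(TrialEvent(t, 0.0, "block_start", {"episode": ep}))
        for w in range(2 * windows_per_material):
            material = order[w % 2]
            task_id = f"study1_{material}"
            idx = counters[material]
            counters[material] += 1
            base = {"task_id": task_id, "level": None, "trial_index": idx, "episode": ep}
            events.append(
                TrialEvent(t, window_s, "stimulus", {**base, "role": "study_window"})
            )
            t += window_s
            events.append(TrialEvent(t, question_s, "stimulus", {**base, "role": "question"}))
            rt = float(RT_QUESTION.draw(rng)[0])
            rt = min(rt, question_s - 0.2)
            events.append(
                TrialEvent(t + rt, 0.0, "keypress", {**base, "role": "answer"})
            )
            t += question_s
            events.append(
                TrialEvent(t, rating_s, "rating_prompt", {**base, "value": None})
            )
            t += rating_s
        events.append(TrialEvent(t, 0.0, "block_end", {"episode": ep}))
    blocks = [
        TaskSpec("study1_comic", None, {"window_s": window_s}),
        TaskSpec("study1_theorem", None, {"window_s": window_s}),
    ]
    sched = SessionSchedule(subject_id, events, blocks)
    sched.total_duration_s = t
    return sched


# ---------------------------------------------------------------------------
# n-back
# ---------------------------------------------------------------------------

def build_nback_block(
    level_n: int,
    n_trials: int,
    rng_seed: int,
    isi_s: float = 2.0,
    stim_s: float = 0.5,
    match_p: float = 0.3,
    rt: ReactionTimes = RT_NBACK,
) -> SessionSchedule:
    """One n-back block: a new digit every ``isi_s`` (2000 ms), identity
    matching against the digit *n* positions back, keypress inside each
    inter-stimulus interval.  The digit alphabet excludes 7."""
    if level_n not in (1, 2, 3):
        raise ValueError(f"level_n must be in {{1,2,3}}, got {level_n}")
    if n_trials < level_n + 1:
        raise ValueError(f"n_trials must be >= level_n + 1, got {n_trials}")
    rng = np.random.default_rng(rng_seed)
    digits: list[int] = []
    events: list[TrialEvent] = [
        TrialEvent(0.0, 0.0, "block_start", {"task_id": "nback", "level": level_n})
    ]
    rts = rt.draw(rng, n_trials)
    # error rate grows with level; only recorded as a correctness flag
    p_err = {1: 0.05, 2: 0.10, 3: 0.20}[level_n]
    for i in range(n_trials):
        if i >= level_n and rng.random() < match_p:
            digit = digits[i - level_n]
        else:
            digit = int(rng.choice(NBACK_DIGITS))
        digits.append(digit)
        is_match = i >= level_n and digit == digits[i - level_n]
        correct = bool(rng.random() >= p_err)
        base = {"task_id": "nback", "level": level_n, "trial_index": i}
        onset = i * isi_s
        events.append(
            TrialEvent(
                onset, stim_s, "stimulus",
                {**base, "role": "digit", "digit": digit, "is_match": is_match},
            )
        )
        events.append(
            TrialEvent(
                onset + float(rts[i]), 0.0, "keypress",
                {**base, "role": "response",
                 "value": "yes" if (is_match == correct) else "no",
                 "correct": correct},
            )
        )
    t_end = n_trials * isi_s
    events.append(
        TrialEvent(t_end, 2.0, "rating_prompt",
                   {"task_id": "nback", "level": level_n, "value": None})
    )
    events.append(TrialEvent(t_end + 2.0, 0.0, "block_end", {"task_id": "nback", "level": level_n}))
    spec = TaskSpec("nback", level_n, {"isi_s": isi_s, "stim_s": stim_s})
    sched = SessionSchedule("fragment", events, [spec])
    sched.total_duration_s = t_end + 2.0
    return sched


# ---------------------------------------------------------------------------
# reading span
# ---------------------------------------------------------------------------

def build_readingspan_block(
    span_length: int,
    n_spans: int,
    rng_seed: int,
    fixation_s: float = 0.5,
    letter_s: float = 1.0,
    rt: ReactionTimes = RT_SENTENCE,
) -> SessionSchedule:
    """One reading-span block: spans of ``span_length`` sentence-letter pairs.

    Each item cycles sentence (self-paced verification) -> keypress ->
    500-ms fixation -> 1000-ms letter; letters are drawn without replacement
    within a span from the 9-letter set.
    """
    if span_length not in (2, 4, 6):
        raise ValueError(f"span_length must be in {{2,4,6}}, got {span_length}")
    if n_spans < 1:
        raise ValueError("n_spans must be >= 1")
    level = {2: 1, 4: 2, 6: 3}[span_length]
    rng = np.random.default_rng(rng_seed)
    events: list[TrialEvent] = [
        TrialEvent(0.0, 0.0, "block_start", {"task_id": "reading_span", "level": level})
    ]
    t = 0.0
    trial = 0
    for span in range(n_spans):
        letters = rng.choice(len(READING_SPAN_LETTERS), size=span_length, replace=False)
        for j in range(span_length):
            base = {"task_id": "reading_span", "level": level,
                    "trial_index": trial, "span": span}
            read_s = float(rt.draw(rng)[0])
            events.append(
                TrialEvent(t, read_s, "stimulus",
                           {**base, "role": "sentence", "truth": bool(rng.random() < 0.5)})
            )
            kp = t + read_s
            events.append(
                TrialEvent(kp, 0.0, "keypress",
                           {**base, "role": "verification",
                            "correct": bool(rng.random() >= 0.05 + 0.03 * level)})
            )
            events.append(TrialEvent(kp, fixation_s, "fixation", base.copy()))
            events.append(
                TrialEvent(kp + fixation_s, letter_s, "stimulus",
                           {**base, "role": "letter",
                            "letter": READING_SPAN_LETTERS[int(letters[j])]})
            )
            t = kp + fixation_s + letter_s
            trial += 1
        # recall screen at span end (self-paced, no EEG analysis window)
        recall_s = 1.5 + 0.8 * span_length
        events.append(
            TrialEvent(t, recall_s, "stimulus",
                       {"task_id": "reading_span", "level": level, "span": span,
                        "role": "recall"})
        )
        t += recall_s
    events.append(
        TrialEvent(t, 2.0, "rating_prompt",
                   {"task_id": "reading_span", "level": level, "value": None})
    )
    events.append(TrialEvent(t + 2.0, 0.0, "block_end", {"task_id": "reading_span", "level": level}))
    spec = TaskSpec("reading_span", level,
                    {"fixation_s": fixation_s, "letter_s": letter_s})
    sched = SessionSchedule("fragment", events, [spec])
    sched.total_duration_s = t + 2.0
    return sched


# ---------------------------------------------------------------------------
# algebra word problems
# ---------------------------------------------------------------------------

def _subtraction_problem(level: int, rng: np.random.Generator) -> dict:
    # x = a ; x = a - b ; x = (a - b) - (c - d); all four numbers always shown
    while True:
        a, b, c, d = (int(v) for v in rng.integers(1, 10, size=4))
        if level == 1:
            answer = a
        elif level == 2:
            if a <= b:
                continue
            answer = a - b
        else:
            if a <= b or c <= d or (a - b) <= (c - d):
                continue
            answer = (a - b) - (c - d)
        return {"params": {"a": a, "b": b, "c": c, "d": d},
                "givens": [a, b, c, d], "answer": float(answer)}


def _fraction_problem(level: int, rng: np.random.Generator) -> dict:
    # x = c*a/b ; x = c*a/b + d*a/b ; x = c*a/b + d*e/f
    # four numerical pieces at every level: fractions count as one piece,
    # distractor numbers pad the easier levels
    a = int(rng.integers(1, 7))
    b = int(rng.integers(a + 1, 10))
    c = int(rng.integers(2, 10))
    d = int(rng.integers(2, 10))
    e = int(rng.integers(1, 7))
    f = int(rng.integers(e + 1, 10))
    frac_ab = f"{a}/{b}"
    frac_ef = f"{e}/{f}"
    if level == 1:
        answer = Fraction(c * a, b)
        givens = [frac_ab, c, d, int(rng.integers(2, 10))]
        params = {"a": a, "b": b, "c": c}
    elif level == 2:
        answer = Fraction(c * a, b) + Fraction(d * a, b)
        givens = [frac_ab, c, d, int(rng.integers(2, 10))]
        params = {"a": a, "b": b, "c": c, "d": d}
    else:
        answer = Fraction(c * a, b) + Fraction(d * e, f)
        givens = [frac_ab, c, d, frac_ef]
        params = {"a": a, "b": b, "c": c, "d": d, "e": e, "f": f}
    return {"params": params, "givens": givens, "answer": float(answer)}


_PROBLEM_FRAME = (
    "A workshop stores {0} boxes on the first shelf, {1} boxes on the second "
    "shelf, {2} boxes on the third shelf and {3} boxes on the fourth shelf."
)


def build_wordproblem_block(
    task_id: str,
    level: int,
    n_problems: int,
    rng_seed: int,
    fixation_s: float = 0.5,
) -> SessionSchedule:
    """One word-problem block (subtraction or fraction problems).

    Each problem is self-paced: fact page -> keypress -> problem statement ->
    keypress -> four-option multiple choice -> keypress -> 500-ms fixation.
    Every problem carries exactly four numerical givens; no feedback events.
    """
    if task_id not in ("subtraction", "fraction"):
        raise ValueError(f"task_id must be subtraction|fraction, got {task_id!r}")
    if level not in (1, 2, 3):
        raise ValueError(f"level must be in 1-3, got {level}")
    if n_problems < 1:
        raise ValueError("n_problems must be >= 1")
    rng = np.random.default_rng(rng_seed)
    make = _subtraction_problem if task_id == "subtraction" else _fraction_problem
    events: list[TrialEvent] = [
        TrialEvent(0.0, 0.0, "block_start", {"task_id": task_id, "level": level})
    ]
    t = 0.0
    p_err = {1: 0.05, 2: 0.12, 3: 0.25}[level]
    for i in range(n_problems):
        prob = make(level, rng)
        base = {"task_id": task_id, "level": level, "trial_index": i}
        fact_s = float(RT_FACT.draw(rng)[0])
        events.append(
            TrialEvent(t, fact_s, "stimulus",
                       {**base, "role": "fact",
                        "text": _PROBLEM_FRAME.format(*prob["givens"]),
                        "givens": [str(g) for g in prob["givens"]]})
        )
        t += fact_s
        events.append(TrialEvent(t, 0.0, "keypress", {**base, "role": "advance"}))
        prob_s = float(RT_PROBLEM.draw(rng)[0])
        events.append(
            TrialEvent(t, prob_s, "stimulus",
                       {**base, "role": "problem",
                        "params": prob["params"], "answer": prob["answer"]})
        )
        t += prob_s
        events.append(TrialEvent(t, 0.0, "keypress", {**base, "role": "next"}))
        choice_s = float(RT_CHOICE.draw(rng)[0])
        events.append(
            TrialEvent(t, choice_s, "stimulus",
                       {**base, "role": "options", "n_options": 4})
        )
        t += choice_s
        correct = bool(rng.random() >= p_err)
        events.append(
            TrialEvent(t, 0.0, "keypress", {**base, "role": "choice", "correct": correct})
        )
        events.append(TrialEvent(t, fixation_s, "fixation", base.copy()))
        t += fixation_s
        # per-trial load rating for the learning tasks
        events.append(
            TrialEvent(t, 2.0, "rating_prompt", {**base, "value": None})
        )
        t += 2.0
    events.append(TrialEvent(t, 0.0, "block_end", {"task_id": task_id, "level": level}))
    spec = TaskSpec(task_id, level, {"fixation_s": fixation_s})
    sched = SessionSchedule("fragment", events, [spec])
    sched.total_duration_s = t
    return sched


# ---------------------------------------------------------------------------
# Study-2 session composition
# ---------------------------------------------------------------------------

def build_study2_session(
    subject_id: str,
    rng_seed: int,
    nback_trials: int = 48,
    rspan_letters: int = 24,
    n_problems: int = 10,
    gap_s: float = 5.0,
) -> SessionSchedule:
    """Full four-task session: working-memory tasks first (classifier
    training), then the two learning tasks, every task running its three
    difficulty levels in simple-to-complex order.  ``rspan_letters`` is the
    target letter count per reading-span level, so trial counts stay
    comparable across span lengths."""
    rng = np.random.default_rng(rng_seed)
    seeds = iter(rng.integers(0, 2**31 - 1, size=16))
    frags: list[SessionSchedule] = []
    for level in (1, 2, 3):
        frags.append(build_nback_block(level, nback_trials, int(next(seeds))))
    for level in (1, 2, 3):
        span = SPAN_FOR_LEVEL[level]
        n_spans = max(1, int(np.ceil(rspan_letters / span)))
        frags.append(build_readingspan_block(span, n_spans, int(next(seeds))))
    for task in ("subtraction", "fraction"):
        for level in (1, 2, 3):
            frags.append(build_wordproblem_block(task, level, n_problems, int(next(seeds))))
    return SessionSchedule.concatenate(subject_id, frags, gap_s=gap_s)


# ---------------------------------------------------------------------------
# trial anchors shared by the generator and the preprocessing stage
# ---------------------------------------------------------------------------

@dataclass
class TrialAnchors:
    """Per-trial time anchors needed for workload gating and interval cuts."""

    task_id: str
    level: int | None
    trial_index: int
    active_start_s: float   # onset of the load-imposing segment
    active_end_s: float     # its natural end (usually a keypress)
    rest_start_s: float | None  # raw rest-segment bounds (pre exclusion guard)
    rest_end_s: float | None
    payload: dict


def iter_trials(schedule: SessionSchedule, task_id: str) -> list[TrialAnchors]:
    """Enumerate analysable trials of *task_id* with their interval anchors.

    The anchors implement the per-task rules: for the n-back, activation runs
    from digit onset to the response keypress and rest from the keypress to
    the next digit; for the reading span, activation is the letter
    presentation and rest the post-verification fixation gap; for the word
    problems, activation is the problem statement (ended by the first
    following keypress) and rest the post-choice fixation.
    """
    if task_id in STUDY1_TASKS:
        return [
            TrialAnchors(task_id, None, e.trial_index, e.onset_s, e.end_s, None, None, e.payload)
            for e in schedule.events
            if e.kind == "stimulus" and e.role == "study_window" and e.task_id == task_id
        ]
    if task_id not in STUDY2_TASKS:
        raise ValueError(f"unknown task_id {task_id!r}")

    ev = [e for e in schedule.events if e.task_id == task_id]
    out: list[TrialAnchors] = []
    if task_id == "nback":
        stims = [e for e in ev if e.role == "digit"]
        kps = {(e.level, e.trial_index): e for e in ev if e.kind == "keypress"}
        isi = 2.0
        for i, s in enumerate(stims):
            kp = kps.get((s.level, s.trial_index))
            if kp is None:
                continue
            nxt = None
            if i + 1 < len(stims) and stims[i + 1].level == s.level:
                nxt = stims[i + 1].onset_s
            if nxt is None:
                nxt = s.onset_s + isi
            out.append(
                TrialAnchors("nback", s.level, s.trial_index, s.onset_s, kp.onset_s,
                             kp.onset_s, nxt, s.payload)
            )
    elif task_id == "reading_span":
        letters = [e for e in ev if e.role == "letter"]
        kps = {(e.level, e.trial_index): e for e in ev
               if e.kind == "keypress" and e.role == "verification"}
        for letter in letters:
            kp = kps.get((letter.level, letter.trial_index))
            if kp is None:
                continue
            out.append(
                TrialAnchors("reading_span", letter.level, letter.trial_index,
                             letter.onset_s, letter.end_s, kp.onset_s, letter.onset_s,
                             letter.payload)
            )
    else:  # word problems
        problems = [e for e in ev if e.role == "problem"]
        kp_by_trial: dict[tuple, dict[str, TrialEvent]] = {}
        for e in ev:
            if e.kind == "keypress":
                kp_by_trial.setdefault((e.level, e.trial_index), {})[e.payload["role"]] = e
        fix = {(e.level, e.trial_index): e for e in ev if e.kind == "fixation"}
        for p in problems:
            key = (p.level, p.trial_index)
            kps = kp_by_trial.get(key, {})
            if "next" not in kps or "choice" not in kps:
                continue
            fx = fix.get(key)
            rest_end = fx.end_s if fx is not None else kps["choice"].onset_s + 0.5
            out.append(
                TrialAnchors(task_id, p.level, p.trial_index, p.onset_s,
                             kps["next"].onset_s, kps["choice"].onset_s, rest_end,
                             p.payload)
            )
    return out
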