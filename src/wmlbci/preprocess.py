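"""Recording clean-up and window extraction.

Implements the three analysis-window rules:

* EOG regression — least-squares removal of the ocular contribution from
  every EEG channel, coefficients estimated on the full recording;
* per-trial activation/rest interval pairs with the keypress exclusion
  guard: no returned sample lies within 125 ms of any keypress, and every
  activation interval ends at least 125 ms before the following keypress;
* fixed 15-s epoching of the 45-s study windows, dropping whole windows
  flagged as artifact-contaminated.

Interval bounds are converted to half-open sample ranges by ceiling the
start and flooring the end, so the exclusion zones are never sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import SessionSchedule, TrialEvent
from .recording import EOG_CHANNELS, EEGRecording
from .schedules import iter_trials

log = logging.getLogger(__name__)

KEYPRESS_GUARD_S = 0.125
MIN_INTERVAL_S = 0.25


# ---------------------------------------------------------------------------
# EOG regression
# ---------------------------------------------------------------------------

def regress_out_eog(
    recording: EEGRecording,
    eog_channels: tuple[str, ...] = EOG_CHANNELS,
    missing: str = "warn",
) -> EEGRecording:
    """Subtract the least-squares projection of each EEG channel onto the EOG
    channels (coefficients from the full-recording covariance).  EOG channels
    are retained unchanged; the residual EEG is uncorrelated with the EOG."""
    present = [c for c in eog_channels if c in recording.channels]
    if not present:
        if missing == "error":
            raise ValueError("no EOG channel present")
        log.warning("no EOG channel present; recording returned unchanged")
        return recording.copy()
    rec = recording.copy()
    eog_rows = [rec.channel_index(c) for c in present]
    eeg_rows = [i for i in range(len(rec.channels)) if i not in eog_rows]
    eog = rec.signal[eog_rows]
    eeg = rec.signal[eeg_rows]
    eog_c = eog - eog.mean(axis=1, keepdims=True)
    eeg_c = eeg - eeg.mean(axis=1, keepdims=True)
    # B solves (eog_c eog_c^T) B = eog_c eeg_c^T; pinv keeps zero-variance
    # regressors harmless (their coefficient collapses to zero)
    gram = eog_c @ eog_c.T
    cross = eog_c @ eeg_c.T
    coeff = np.linalg.pinv(gram) @ cross          # (n_eog, n_eeg)
    rec.signal[eeg_rows] = eeg - coeff.T @ eog_c
    return rec


# ---------------------------------------------------------------------------
# interval pairs
# ---------------------------------------------------------------------------

@dataclass
class Interval:
    """Half-open analysis window [start, end) quantized to the sample grid."""

    start_s: float
    end_s: float
    i0: int
    i1: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def n_samples(self) -> int:
        return self.i1 - self.i0


@dataclass
class IntervalPair:
    """Per-trial activation interval I_a and rest interval I_r."""

    task_id: str
    level: int | None
    trial_index: int
    activation: Interval
    rest: Interval
    payload: dict = field(default_factory=dict)


def _quantize(start_s: float, end_s: float, rate: float) -> Interval | None:
    i0 = int(np.ceil(start_s * rate - 1e-9))
    i1 = int(np.floor(end_s * rate + 1e-9))
    if i1 <= i0:
        return None
    return Interval(i0 / rate, i1 / rate, i0, i1)


def _violates_guard(iv: Interval, kp_times: np.ndarray, guard_s: float) -> bool:
    if not len(kp_times):
        return False
    # open overlap test between [start, end) and (kp-guard, kp+guard)
    return bool(np.any((kp_times - guard_s < iv.end_s - 1e-12)
                       & (kp_times + guard_s > iv.start_s + 1e-12)))


def _push_start(start_s: float, kp_times: np.ndarray, guard_s: float) -> float:
    """Move an interval start out of any keypress exclusion zone it touches."""
    if not len(kp_times):
        return start_s
    for _ in range(8):
        near = kp_times[(kp_times - guard_s < start_s + 1e-12)
                        & (kp_times + guard_s > start_s + 1e-12)]
        if not len(near):
            break
        start_s = float(near.max()) + guard_s
    return start_s


def extract_interval_pairs(
    recording: EEGRecording | SessionSchedule,
    task_id: str,
    rate: float | None = None,
    min_duration_s: float = MIN_INTERVAL_S,
    guard_s: float = KEYPRESS_GUARD_S,
) -> list[IntervalPair]:
    """Cut the per-trial activation/rest interval pair for every trial of
    *task_id*, discarding any trial whose intervals would be shorter than
    ``min_duration_s`` or would touch a keypress exclusion zone."""
    if isinstance(recording, EEGRecording):
        events: list[TrialEvent] = recording.events
        rate = recording.rate
        container: SessionSchedule | EEGRecording = recording
    else:
        events = recording.events
        if rate is None:
            raise ValueError("rate is required when extracting from a schedule")
        container = recording
    sched = recording if isinstance(recording, SessionSchedule) else \
        SessionSchedule(getattr(container, "subject_id", ""), list(events))
    trials = iter_trials(sched, task_id)
    if not trials:
        raise ValueError(f"no trials of task {task_id!r} in the event stream")
    kp_times = np.array([e.onset_s for e in events if e.kind == "keypress"])

    pairs: list[IntervalPair] = []
    n_discarded = 0
    for tr in trials:
        # activation: from the activation onset (pushed out of any exclusion
        # zone) to the natural end, trimmed to 125 ms before the first
        # keypress falling inside it
        a_start = _push_start(tr.active_start_s, kp_times, guard_s)
        a_end = tr.active_end_s
        inside = kp_times[(kp_times > a_start) & (kp_times <= a_end + guard_s)]
        if len(inside):
            a_end = min(a_end, float(inside.min()) - guard_s)
        act = _quantize(a_start, a_end, rate)
        # rest: from 125 ms after the anchoring keypress to the rest end
        if tr.rest_start_s is None or tr.rest_end_s is None:
            rest = None
        else:
            r_start = _push_start(tr.rest_start_s, kp_times, guard_s)
            r_end = tr.rest_end_s
            inside_r = kp_times[(kp_times > r_start) & (kp_times <= r_end + guard_s)]
            if len(inside_r):
                r_end = min(r_end, float(inside_r.min()) - guard_s)
            rest = _quantize(r_start, r_end, rate)
        if act is None or rest is None:
            n_discarded += 1
            continue
        ok = True
        for iv in (act, rest):
            if iv.duration_s < min_duration_s - 1e-12:
                ok = False
            elif _violates_guard(iv, kp_times, guard_s):
                ok = False
        if not ok:
            n_discarded += 1
            continue
        pairs.append(IntervalPair(task_id, tr.level, tr.trial_index, act, rest, tr.payload))
    if n_discarded:
        log.info("extract_interval_pairs(%s): discarded %d/%d trials",
                 task_id, n_discarded, len(trials))
    if not pairs:
        raise ValueError(f"no valid trials of task {task_id!r} after interval cuts")
    return pairs


# ---------------------------------------------------------------------------
# Study-1 epoching
# ---------------------------------------------------------------------------

@dataclass
class Epoch:
    """Fixed-length signal slice with provenance."""

    signal: np.ndarray  # channels x samples
    start_s: float
    end_s: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")


def segment_study_windows(
    recording: EEGRecording,
    window_len_s: float = 45.0,
    epoch_len_s: float = 15.0,
    artifact_p2p_uv: float = 150.0,
) -> list[Epoch]:
    """Split each artifact-free study window into non-overlapping fixed
    epochs tagged with the material type; windows whose peak-to-peak
    amplitude exceeds ``artifact_p2p_uv`` on any EEG channel are dropped
    whole."""
    n_epochs = window_len_s / epoch_len_s
    if abs(n_epochs - round(n_epochs)) > 1e-9:
        raise ValueError(
            f"window_len_s={window_len_s} not divisible by epoch_len_s={epoch_len_s}"
        )
    n_epochs = int(round(n_epochs))
    eeg_rows = [i for i, c in enumerate(recording.channels) if c not in EOG_CHANNELS]
    windows = [e for e in recording.events
               if e.kind == "stimulus" and e.role == "study_window"]
    if not windows:
        raise ValueError("no study-window events in recording")
    epochs: list[Epoch] = []
    n_dropped = 0
    for w in windows:
        sl = recording.slice(w.onset_s, w.onset_s + window_len_s)
        p2p = sl[eeg_rows].max(axis=1) - sl[eeg_rows].min(axis=1)
        if np.any(p2p > artifact_p2p_uv):
            n_dropped += 1
            continue
        material = w.task_id
        for k in range(n_epochs):
            t0 = w.onset_s + k * epoch_len_s
            t1 = t0 + epoch_len_s
            epochs.append(
                Epoch(recording.slice(t0, t1), t0, t1,
                      {"task_id": material, "material": material.removeprefix("study1_"),
                       "window_index": w.trial_index, "epoch_index": k,
                       "episode": w.payload.get("episode")})
            )
    if n_dropped:
        log.info("segment_study_windows: dropped %d artifact windows", n_dropped)
    return epochs
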