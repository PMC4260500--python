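"""Multichannel EEG container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import SessionSchedule, TrialEvent

DEFAULT_EEG_CHANNELS = ("F3", "Fz", "F4", "FC1", "FC2", "CP1", "CP2", "P3", "Pz", "P4")
EOG_CHANNELS = ("VEOG", "HEOG")


@dataclass
class EEGRecording:
    """channels x samples signal (microvolts) with rate, labels and events."""

    signal: np.ndarray
    rate: float
    channels: list[str]
    events: list[TrialEvent] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError("channel count must equal label count")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def get(self, label: str) -> np.ndarray:
        return self.signal[self.channel_index(label)]

    def slice(self, start_s: float, end_s: float, channels: list[str] | None = None) -> np.ndarray:
        i0 = int(np.ceil(start_s * self.rate - 1e-9))
        i1 = int(np.floor(end_s * self.rate + 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        if channels is None:
            return self.signal[:, i0:i1]
        rows = [self.channel_index(c) for c in channels]
        return self.signal[rows][:, i0:i1]

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.signal.copy(), self.rate, list(self.channels),
                            list(self.events), self.subject_id)

    # -- text container ----------------------------------------------------
    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "signal.csv", self.signal.T, delimiter=",",
                   header=",".join(self.channels), comments="", fmt="%.6f")
        (directory / "recording.json").write_text(json.dumps(
            {"rate": self.rate, "channels": self.channels, "subject_id": self.subject_id}
        ))
        SessionSchedule(self.subject_id, list(self.events)).to_files(directory)

    @staticmethod
    def from_dir(directory: str | Path) -> "EEGRecording":
        directory = Path(directory)
        meta = json.loads((directory / "recording.json").read_text())
        sig = np.loadtxt(directory / "signal.csv", delimiter=",", skiprows=1).T
        sched = SessionSchedule.from_files(directory)
        return EEGRecording(sig, meta["rate"], meta["channels"], sched.events,
                            meta["subject_id"])
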