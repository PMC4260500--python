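"""%ERD/ERS and band-power feature construction.

The event-related (de)synchronization ratio compares the power in the
activation interval against the rest interval of the same trial:

    %ERD/ERS = (P_activation - P_rest) / P_rest * 100

(negative = desynchronization).  Because it is a pure power ratio taken
within one trial, any multiplicative slow gain acting on the whole signal
cancels — the property that makes it robust against session drift under a
fixed simple-to-complex task order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Epoch, IntervalPair
from .recording import DEFAULT_EEG_CHANNELS, EEGRecording
from .spectral import FEATURE_FREQS, band_power, epoch_spectrum

log = logging.getLogger(__name__)


def erd_ers(power_activation: float | np.ndarray, power_reference: float | np.ndarray):
    """Percent event-related desynchronization/synchronization."""
    pa = np.asarray(power_activation, dtype=float)
    pr = np.asarray(power_reference, dtype=float)
    if np.any(pr <= 0):
        raise ValueError("reference power must be > 0")
    out = (pa - pr) / pr * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class FeatureMatrix:
    """trials x features values with names, labels, and per-trial provenance."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature-name count must equal column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("label count must equal row count")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return FeatureMatrix(
            self.values[idx], list(self.feature_names),
            None if self.labels is None else self.labels[idx],
            [self.provenance[i] for i in idx],
        )

    def with_labels(self, labels: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.values, list(self.feature_names),
                             np.asarray(labels), list(self.provenance))

    def to_files(self, path_prefix: str | Path) -> None:
        path_prefix = Path(path_prefix)
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path_prefix.with_suffix(".tsv"), sep="\t", index=False)
        path_prefix.with_suffix(".json").write_text(json.dumps(self.provenance, indent=1))

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        names = parts[0].feature_names
        for p in parts:
            if p.feature_names != names:
                raise ValueError("feature-name mismatch between parts")
        labels = None
        if all(p.labels is not None for p in parts):
            labels = np.concatenate([p.labels for p in parts])
        return FeatureMatrix(
            np.vstack([p.values for p in parts]), list(names), labels,
            [pr for p in parts for pr in p.provenance],
        )


def build_crosstask_features(
    recording: EEGRecording,
    interval_pairs: list[IntervalPair],
    electrodes: tuple[str, ...] = DEFAULT_EEG_CHANNELS,
    freqs: tuple[int, ...] = FEATURE_FREQS,
    ar_order: int = 16,
) -> FeatureMatrix:
    """One %ERD/ERS row per trial: Burg PSD on I_a and I_r separately, per
    electrode and single frequency (default 10 x 10 = 100 columns).  The
    feature definition is identical across all tasks and subjects."""
    if not interval_pairs:
        raise ValueError("no interval pairs given")
    names = [f"{el}:{f}Hz" for el in electrodes for f in freqs]
    rows: list[np.ndarray] = []
    prov: list[dict] = []
    n_dropped = 0
    for pair in interval_pairs:
        try:
            sa = recording.signal[:, pair.activation.i0:pair.activation.i1]
            sr = recording.signal[:, pair.rest.i0:pair.rest.i1]
            rows_idx = [recording.channel_index(el) for el in electrodes]
            spec_a = epoch_spectrum(sa[rows_idx], recording.rate, list(electrodes),
                                    order=ar_order, eval_freqs=freqs)
            spec_r = epoch_spectrum(sr[rows_idx], recording.rate, list(electrodes),
                                    order=ar_order, eval_freqs=freqs)
            if np.any(spec_r.power <= 0):  # impossible for a proper AR spectrum
                raise ValueError("non-positive reference power")
            row = erd_ers(spec_a.power, spec_r.power).ravel()
        except ValueError:
            n_dropped += 1
            continue
        rows.append(row)
        prov.append({"task_id": pair.task_id, "level": pair.level,
                     "trial_index": pair.trial_index,
                     "t_activation": [pair.activation.start_s, pair.activation.end_s],
                     "t_rest": [pair.rest.start_s, pair.rest.end_s]})
    if n_dropped:
        log.info("build_crosstask_features: dropped %d trials with failed PSD", n_dropped)
    if not rows:
        raise ValueError("all trials dropped during feature construction")
    return FeatureMatrix(np.vstack(rows), names, None, prov)


def build_study1_features(
    epochs: list[Epoch],
    recording_rate: float,
    channels: list[str],
    electrodes: tuple[str, ...] = DEFAULT_EEG_CHANNELS,
    band: str = "alpha",
    ar_order: int = 16,
) -> FeatureMatrix:
    """Raw alpha band power per electrode for each fixed-length epoch,
    labelled by material type (the within-task design predates the ratio
    features; only alpha carried material differences, so theta is refused)."""
    if band != "alpha":
        raise ValueError(
            "within-task mode uses alpha power only (no theta differences "
            "between the two materials)"
        )
    if not epochs:
        raise ValueError("no epochs given")
    names = [f"{el}:alpha" for el in electrodes]
    rows_idx = [channels.index(el) for el in electrodes]
    rows = []
    labels = []
    prov = []
    for ep in epochs:
        spec = epoch_spectrum(ep.signal[rows_idx], recording_rate, list(electrodes),
                              order=ar_order)
        rows.append(band_power(spec, "alpha"))
        labels.append(ep.provenance.get("material"))
        prov.append(dict(ep.provenance, start_s=ep.start_s, end_s=ep.end_s))
    return FeatureMatrix(np.vstack(rows), names, np.asarray(labels), prov)
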