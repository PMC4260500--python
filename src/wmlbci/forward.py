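"""Synthetic-EEG forward model.

The generator renders a :class:`~wmlbci.events.SessionSchedule` into a
multichannel recording under the oscillatory workload signature the analysis
assumes: a frontal-midline theta source whose amplitude grows with latent
load W and a parietal alpha source whose amplitude shrinks with W,

    x_c(t) = g(t) * [ w_theta_c * A_theta * (1 + k_t W(t)) * osc_theta(t)
                    + w_alpha_c * A_alpha * (1 - k_a W(t)) * osc_alpha(t) ]
             + pink noise + artifacts,

with a multiplicative slow session drift g(t) acting on sources and
background alike (a sensor-gain non-stationarity), W(t) gated per trial by
the activation envelope, optional overload reversal (theta/alpha modulation
signs invert above a load threshold), Poisson blinks weighted onto frontal
channels, and 20-60 Hz EMG bursts centred on keypresses.  Oscillators are
narrowband amplitude-modulated sinusoids so band-power expectations have
closed form; k_a and k_t modulate *amplitude*, so expected power ratios are
the squared factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .events import SessionSchedule
from .recording import DEFAULT_EEG_CHANNELS, EOG_CHANNELS, EEGRecording
from .workload import RatingModel, RatingRecord, WorkloadProfile, generate_ratings, \
    simulate_latent_workload

#: spatial weights of the two sources: theta peaks at the frontal midline,
#: alpha at parietal/centro-parietal sites
THETA_WEIGHTS = {"F3": 0.6, "Fz": 1.0, "F4": 0.6, "FC1": 0.8, "FC2": 0.8,
                 "CP1": 0.3, "CP2": 0.3, "P3": 0.2, "Pz": 0.2, "P4": 0.2}
ALPHA_WEIGHTS = {"F3": 0.25, "Fz": 0.2, "F4": 0.25, "FC1": 0.45, "FC2": 0.45,
                 "CP1": 0.7, "CP2": 0.7, "P3": 0.9, "Pz": 1.0, "P4": 0.9}
BLINK_LEAK = {"F3": 0.35, "Fz": 0.4, "F4": 0.35, "FC1": 0.2, "FC2": 0.2,
              "CP1": 0.08, "CP2": 0.08, "P3": 0.04, "Pz": 0.04, "P4": 0.04}


@dataclass
class ForwardModel:
    """Physical parameters of the synthetic-EEG generator (amplitudes in uV)."""

    channels: tuple[str, ...] = DEFAULT_EEG_CHANNELS + EOG_CHANNELS
    rate: float = 500.0
    theta_hz: float = 6.0
    alpha_hz: float = 10.0
    theta_amp: float = 5.0
    alpha_amp: float = 9.0
    k_t: float = 1.0           # theta amplitude gain per unit load
    k_a: float = 0.8           # alpha amplitude attenuation per unit load
    theta_weights: dict[str, float] = field(default_factory=lambda: dict(THETA_WEIGHTS))
    alpha_weights: dict[str, float] = field(default_factory=lambda: dict(ALPHA_WEIGHTS))
    freq_jitter_hz: float = 0.05
    am_depth: float = 0.1      # oscillator amplitude-modulation depth
    pink_amp: float = 2.5      # rms of the 1/f background per channel
    drift_amp: float = 0.15    # multiplicative slow-gain amplitude d
    drift_period_s: float = 300.0
    blink_rate_hz: float = 0.08
    blink_amp: float = 180.0
    emg_amp: float = 3.0       # rms of the 20-60 Hz keypress burst
    emg_dur_s: float = 0.2

    def __post_init__(self) -> None:
        if self.k_t < 0 or not 0.0 <= self.k_a <= 1.0:
            raise ValueError("k_t must be >= 0 and k_a in [0,1]")
        if any(w < 0 for w in self.theta_weights.values()) or any(
            w < 0 for w in self.alpha_weights.values()
        ):
            raise ValueError("spatial weights must be >= 0")
        if self.rate <= 2 * max(self.theta_hz, self.alpha_hz, 60.0):
            raise ValueError(
                f"rate {self.rate} Hz too low for the modelled frequencies (aliasing)"
            )
        if not 0 <= self.drift_amp < 1:
            raise ValueError("drift_amp must be in [0,1) to keep the gain positive")

    @property
    def eeg_channels(self) -> list[str]:
        return [c for c in self.channels if c not in EOG_CHANNELS]

    def with_(self, **kw) -> "ForwardModel":
        return replace(self, **kw)


def _smoothed_noise(n: int, rate: float, smooth_s: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed by a moving average."""
    w = max(int(round(smooth_s * rate)), 1)
    x = uniform_filter1d(rng.standard_normal(n), size=w, mode="nearest")
    sd = x.std()
    return x / sd if sd > 0 else x


def narrowband_oscillator(
    n: int, rate: float, f0: float, jitter_hz: float, am_depth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude-modulated sinusoid with slow frequency jitter, unit amplitude."""
    f_inst = f0 + jitter_hz * _smoothed_noise(n, rate, 0.5, rng)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / rate + rng.uniform(0.0, 2.0 * np.pi)
    am = 1.0 + am_depth * _smoothed_noise(n, rate, 1.0, rng)
    return np.clip(am, 0.0, None) * np.sin(phase)


def pink_noise(n: int, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise (flat below 1 Hz is approximated by clamping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)  # unit grid, shape only
    scale = 1.0 / np.sqrt(np.maximum(freqs, freqs[1] if n > 1 else 1.0))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return (rms / sd) * x if sd > 0 else x


def workload_envelope(
    schedule: SessionSchedule, profile: WorkloadProfile, n: int, rate: float,
) -> tuple[np.ndarray, list]:
    """Sample-wise latent load W(t): the trial load inside activation spans,
    zero elsewhere.  Returns (W(t), per-trial loads)."""
    loads = simulate_latent_workload(schedule, profile)
    w = np.zeros(n)
    for tl in loads:
        i0 = int(np.ceil(tl.anchors.active_start_s * rate))
        i1 = min(int(np.floor(tl.anchors.active_end_s * rate)), n)
        if i1 > i0:
            w[i0:i1] = tl.w
    return w, loads


def simulate_session(
    schedule: SessionSchedule,
    forward_model: ForwardModel | None = None,
    profile: WorkloadProfile | None = None,
    rating_model: RatingModel | None = None,
    seed: int = 0,
    artifacts: bool = True,
) -> tuple[EEGRecording, list[RatingRecord]]:
    """Render a schedule into an EEG recording plus coupled ratings.

    Fully reproducible from ``seed``: the oscillator phases/jitter, the pink
    background, the drift phase, artifact times and rating noise each consume
    an independent child stream of the seed.
    """
    fm = forward_model or ForwardModel()
    profile = profile or WorkloadProfile()
    rating_model = rating_model or RatingModel()
    ss = np.random.SeedSequence(seed)
    r_theta, r_alpha, r_pink, r_drift, r_art, r_rate = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    n = int(np.ceil(schedule.total_duration_s * fm.rate))
    w_t, loads = workload_envelope(schedule, profile, n, fm.rate)

    theta_mod = 1.0 + fm.k_t * w_t
    alpha_mod = 1.0 - fm.k_a * w_t
    if profile.overload_reversal:
        over = w_t > profile.reversal_threshold
        theta_mod[over] = 1.0 - fm.k_t * w_t[over]
        alpha_mod[over] = 1.0 + fm.k_a * w_t[over]
    np.clip(theta_mod, 0.0, None, out=theta_mod)
    np.clip(alpha_mod, 0.0, None, out=alpha_mod)

    osc_t = narrowband_oscillator(n, fm.rate, fm.theta_hz, fm.freq_jitter_hz,
                                  fm.am_depth, r_theta)
    osc_a = narrowband_oscillator(n, fm.rate, fm.alpha_hz, fm.freq_jitter_hz,
                                  fm.am_depth, r_alpha)
    theta_src = fm.theta_amp * theta_mod * osc_t
    alpha_src = fm.alpha_amp * alpha_mod * osc_a

    if fm.drift_amp > 0:
        t = np.arange(n) / fm.rate
        g = 1.0 + fm.drift_amp * np.sin(
            2.0 * np.pi * t / fm.drift_period_s + r_drift.uniform(0, 2 * np.pi)
        )
    else:
        g = 1.0

    # the slow gain acts like an electrode/sensor drift: it scales the whole
    # recorded signal (sources and background alike), which is exactly the
    # multiplicative non-stationarity the %ERD/ERS ratio is meant to cancel
    sig = np.empty((len(fm.channels), n))
    for ci, ch in enumerate(fm.channels):
        wt = fm.theta_weights.get(ch, 0.0)
        wa = fm.alpha_weights.get(ch, 0.0)
        sig[ci] = g * (wt * theta_src + wa * alpha_src
                       + pink_noise(n, fm.pink_amp, r_pink))

    rec = EEGRecording(sig, fm.rate, list(fm.channels), list(schedule.events),
                       schedule.subject_id)
    if artifacts:
        rec = inject_artifacts(rec, fm, rng=r_art)
    ratings = generate_ratings(schedule, loads, rating_model, r_rate)
    # fill rating_prompt payloads in the recording's event stream
    lookup = {(r.task, r.level, r.index): r.rating for r in ratings}
    block_lookup = {(r.task, r.level): r.rating for r in ratings}
    for e in rec.events:
        if e.kind == "rating_prompt":
            key = (e.task_id, e.level, e.trial_index)
            e.payload["value"] = lookup.get(key, block_lookup.get((e.task_id, e.level)))
    return rec, ratings


def _blink_template(rate: float) -> np.ndarray:
    n = max(int(round(0.3 * rate)), 3)
    return np.hanning(n) ** 2


def inject_artifacts(
    recording: EEGRecording,
    forward_model: ForwardModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Add Poisson blinks (frontal-weighted, driving VEOG) and band-limited
    20-60 Hz EMG bursts centred on every keypress.  Events are preserved."""
    fm = forward_model
    rng = rng if rng is not None else np.random.default_rng(seed)
    rec = recording.copy()
    n = rec.n_samples
    rate = rec.rate

    if fm.blink_amp > 0 and fm.blink_rate_hz > 0:
        tpl = _blink_template(rate) * fm.blink_amp
        n_blinks = rng.poisson(fm.blink_rate_hz * rec.duration_s)
        onsets = np.sort(rng.uniform(0, rec.duration_s, size=n_blinks))
        for t0 in onsets:
            i0 = int(t0 * rate)
            seg = tpl[: max(n - i0, 0)]
            if not len(seg):
                continue
            for ci, ch in enumerate(rec.channels):
                if ch == "VEOG":
                    rec.signal[ci, i0:i0 + len(seg)] += seg
                elif ch == "HEOG":
                    rec.signal[ci, i0:i0 + len(seg)] += 0.1 * seg
                else:
                    rec.signal[ci, i0:i0 + len(seg)] += BLINK_LEAK.get(ch, 0.05) * seg

    if fm.emg_amp > 0:
        kp_times = [e.onset_s for e in rec.events if e.kind == "keypress"]
        if kp_times:
            m = max(int(round(fm.emg_dur_s * rate)), 8)
            sos = butter(4, [20.0, 60.0], btype="bandpass", fs=rate, output="sos")
            env = np.hanning(m)
            eeg_rows = [i for i, c in enumerate(rec.channels) if c not in EOG_CHANNELS]
            for kt in kp_times:
                i0 = int(round((kt - fm.emg_dur_s / 2) * rate))
                burst = sosfiltfilt(sos, rng.standard_normal((len(eeg_rows), 3 * m)),
                                    axis=1)[:, m:2 * m]
                sd = burst.std()
                if sd > 0:
                    burst *= fm.emg_amp / sd
                burst *= env
                j0, j1 = max(i0, 0), min(i0 + m, n)
                if j1 > j0:
                    rec.signal[np.ix_(eeg_rows, range(j0, j1))] += burst[:, j0 - i0: j1 - i0]
    return rec
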