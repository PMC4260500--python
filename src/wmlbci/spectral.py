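"""Burg autoregressive spectral estimation and band power.

The Burg recursion minimizes the summed forward and backward prediction
error at each model order and updates the AR coefficients through the
Levinson recursion; all reflection coefficients lie in (-1, 1), so the
fitted model is always stable, which makes it well suited to the short,
variable-length analysis windows produced by the interval cuts.

Coefficient convention: the fitted model is

    x_t = sum_k a_k x_{t-k} + e_t,   e_t ~ N(0, sigma2),

and the spectral density is evaluated exactly at requested frequencies as

    P(f) = sigma2 / ( rate * | 1 - sum_k a_k exp(-2 pi i f k / rate) |^2 ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: analysis bands (Hz, inclusive integer grids)
BANDS = {"theta": (4, 7), "alpha": (8, 13)}
#: the ten single-frequency features per electrode
FEATURE_FREQS = tuple(range(4, 14))


def _burg_batch(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Burg recursion over a batch of signals.

    Parameters
    ----------
    x : (n_series, n_samples) array
    order : AR model order

    Returns
    -------
    a : (n_series, order) coefficients in the ``x_t = sum a_k x_{t-k}`` convention
    sigma2 : (n_series,) driving-noise variances
    k : (n_series, order) reflection coefficients
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_series, n = x.shape
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    if n <= 2 * order:
        raise ValueError(f"signal length {n} must exceed 2*order={2 * order}")
    e = np.einsum("ij,ij->i", x, x) / n
    if np.any(e <= 0):
        raise ValueError("zero-variance (constant) signal")
    ef = x.copy()
    eb = x.copy()
    a = np.zeros((n_series, order))
    ks = np.zeros((n_series, order))
    for m in range(order):
        efm = ef[:, m + 1:]
        ebm = eb[:, m:-1]
        den = np.einsum("ij,ij->i", efm, efm) + np.einsum("ij,ij->i", ebm, ebm)
        if np.any(den <= 0):
            raise ValueError("prediction error collapsed to zero (degenerate signal)")
        k = -2.0 * np.einsum("ij,ij->i", efm, ebm) / den
        ks[:, m] = k
        prev = a[:, :m].copy()
        a[:, :m] = prev + k[:, None] * prev[:, ::-1]
        a[:, m] = k
        tmp = efm + k[:, None] * ebm
        eb[:, m + 1:] = ebm + k[:, None] * efm
        ef[:, m + 1:] = tmp
        e = e * (1.0 - k * k)
    # flip sign: internal `a` is the polynomial convention (1 + sum a_k z^-k)
    return -a, e, ks


def burg_fit(signal_1d: np.ndarray, order: int) -> tuple[np.ndarray, float, np.ndarray]:
    """Fit an AR(order) model to a 1-D signal by the Burg algorithm.

    Returns ``(coefficients, noise_variance, reflection_coefficients)`` with
    coefficients in the ``x_t = sum_k a_k x_{t-k} + e_t`` convention.
    """
    x = np.asarray(signal_1d, dtype=float)
    if x.ndim != 1:
        raise ValueError("burg_fit expects a 1-D signal")
    a, s2, k = _burg_batch(x[None, :], order)
    return a[0], float(s2[0]), k[0]


def ar_psd(
    coefficients: np.ndarray,
    noise_var: float | np.ndarray,
    rate: float,
    eval_freqs: np.ndarray,
) -> np.ndarray:
    """Evaluate the AR spectral density exactly at the requested frequencies.

    Accepts a single coefficient vector ``(order,)`` or a batch
    ``(n_series, order)``; returns shape ``(n_freqs,)`` or ``(n_series,
    n_freqs)`` accordingly.
    """
    freqs = np.asarray(eval_freqs, dtype=float)
    if np.any(freqs >= rate / 2.0) or np.any(freqs < 0):
        raise ValueError("eval_freqs must lie in [0, rate/2)")
    a = np.asarray(coefficients, dtype=float)
    single = a.ndim == 1
    a = np.atleast_2d(a)
    order = a.shape[1]
    k = np.arange(1, order + 1)
    # denominator polynomial 1 - sum a_k e^{-i 2 pi f k / rate}
    ex = np.exp(-2j * np.pi * np.outer(freqs, k) / rate)  # (n_freqs, order)
    denom = 1.0 - a @ ex.T                                 # (n_series, n_freqs)
    s2 = np.atleast_1d(np.asarray(noise_var, dtype=float))
    psd = s2[:, None] / (rate * np.abs(denom) ** 2)
    return psd[0] if single else psd


@dataclass
class PowerSpectrum:
    """AR spectrum of one epoch: per-channel power on a frequency grid."""

    frequencies: np.ndarray           # (n_freqs,)
    power: np.ndarray                 # (n_channels, n_freqs)
    channels: list[str]
    ar_order: int
    noise_var: np.ndarray             # (n_channels,)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def channel_power(self, channel: str) -> np.ndarray:
        return self.power[self.channels.index(channel)]


def epoch_spectrum(
    signal: np.ndarray,
    rate: float,
    channels: list[str],
    order: int = 16,
    eval_freqs: tuple[int, ...] = FEATURE_FREQS,
    detrend: bool = True,
) -> PowerSpectrum:
    """Burg spectrum of a channels x samples epoch at the feature grid.

    Epochs are linearly detrended and mean-subtracted first so additive
    drift is not misattributed to low-frequency AR poles.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if detrend:
        from scipy.signal import detrend as _detrend

        x = _detrend(x, axis=1, type="linear")
    a, s2, _ = _burg_batch(x, order)
    power = ar_psd(a, s2, rate, np.asarray(eval_freqs, dtype=float))
    return PowerSpectrum(np.asarray(eval_freqs, dtype=float), power, list(channels),
                         order, s2)


def band_power(spectrum: PowerSpectrum, band: str) -> np.ndarray:
    """Mean spectral power over the band's integer frequencies, per channel.

    The mean (rather than the sum) keeps the 4-point theta band and the
    6-point alpha band on a comparable scale.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    grid = spectrum.frequencies
    mask = np.isin(grid, np.arange(lo, hi + 1))
    if mask.sum() != hi - lo + 1:
        raise ValueError(f"band {band} ({lo}-{hi} Hz) not fully contained in the grid")
    return spectrum.power[:, mask].mean(axis=1)
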