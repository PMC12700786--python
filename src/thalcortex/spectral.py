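"""Time-frequency decomposition, power spectra and band aggregation.

Epoched data are decomposed from 2-40 Hz with complex Morlet wavelets
(5 cycles, 1 Hz grid), giving power and phase from a single transform.
Power spectra are normalised per channel as percent of total 2-40 Hz power,
making spectra comparable across patients and insensitive to overall scale.
Band summaries use the canonical theta (3-7 Hz), alpha (8-12 Hz) and beta
(13-30 Hz) groupings with inclusive bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .epochs import EpochSet


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError("band lo must be below hi")


THETA = BandSpec("theta", 3.0, 7.0)
ALPHA = BandSpec("alpha", 8.0, 12.0)
BETA = BandSpec("beta", 13.0, 30.0)
BANDS = (THETA, ALPHA, BETA)

DEFAULT_FREQS = np.arange(2.0, 41.0, 1.0)


@dataclass
class TFDecomposition:
    """Complex wavelet coefficients: trials x channels x freqs x samples."""

    coeffs: np.ndarray
    freqs: np.ndarray
    rate: float
    times: np.ndarray            # seconds relative to the epoch anchor
    channel_labels: list[str]
    n_cycles: float
    valid: np.ndarray = field(default=None)  # freqs x samples edge mask

    def __post_init__(self):
        if self.valid is None:
            half = np.ceil(self.n_cycles / (2 * self.freqs) * self.rate).astype(int)
            n = self.coeffs.shape[-1]
            self.valid = np.ones((self.freqs.size, n), dtype=bool)
            for i, h in enumerate(half):
                self.valid[i, :h] = False
                if h > 0:
                    self.valid[i, n - h:] = False

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class PowerSpectrum:
    """Per-channel power: raw (µV²) or normalised (% of total 2-40 Hz power)."""

    values: np.ndarray           # channels x freqs
    freqs: np.ndarray
    channel_labels: list[str]
    normalised: bool = False


def decompose(epochs: EpochSet, freqs: np.ndarray | None = None,
              n_cycles: float = 5.0) -> TFDecomposition:
    """Morlet wavelet decomposition of an epoch set.

    Samples within half a wavelet length of either epoch edge are flagged
    invalid per frequency; static averages exclude them, sliding-window
    series keep them (the epoch padding protects the analysis range).
    """
    freqs = np.asarray(freqs if freqs is not None else DEFAULT_FREQS, dtype=float)
    if freqs.min() < 2.0 or freqs.max() > 40.0:
        raise ValueError("frequency grid must lie within 2-40 Hz")
    # longest wavelet as built by mne: +-5 temporal sigmas at the lowest freq
    sigma_t = n_cycles / (2.0 * np.pi * freqs.min())
    longest = 2 * int(np.ceil(5.0 * sigma_t * epochs.rate)) - 1
    if epochs.data.shape[-1] < longest:
        raise ValueError(
            f"epoch ({epochs.data.shape[-1]} samples) shorter than the longest "
            f"wavelet ({longest} samples at {freqs.min():g} Hz); restrict the "
            f"frequency grid or lengthen the epochs")
    coeffs = tfr_array_morlet(epochs.data, sfreq=epochs.rate, freqs=freqs,
                              n_cycles=n_cycles, output="complex",
                              zero_mean=True, verbose="error")
    times = epochs.window[0] + np.arange(epochs.data.shape[-1]) / epochs.rate
    return TFDecomposition(coeffs, freqs, epochs.rate, times,
                           list(epochs.channel_labels), n_cycles)


def power_spectrum(tf: TFDecomposition) -> PowerSpectrum:
    """Mean squared magnitude over valid samples, then over trials."""
    p = np.abs(tf.coeffs) ** 2                       # trials x ch x f x t
    w = tf.valid[None, None, :, :]
    sums = (p * w).sum(axis=-1)
    counts = tf.valid.sum(axis=-1)[None, None, :]
    per_trial = sums / counts                        # trials x ch x f
    return PowerSpectrum(per_trial.mean(axis=0), tf.freqs.copy(),
                         list(tf.channel_labels), normalised=False)


def normalize_power(ps: PowerSpectrum) -> PowerSpectrum:
    """Express each channel's spectrum as percent of its total 2-40 Hz power."""
    total = ps.values.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total power in at least one channel")
    return PowerSpectrum(100.0 * ps.values / total, ps.freqs.copy(),
                         list(ps.channel_labels), normalised=True)


def band_indices(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    idx = np.flatnonzero((freqs >= band.lo) & (freqs <= band.hi))
    if idx.size == 0:
        raise ValueError(f"band {band.name} outside the frequency grid")
    return idx


def band_average(values: np.ndarray, freqs: np.ndarray, band: BandSpec,
                 axis: int = -1) -> np.ndarray:
    """Unweighted mean over grid frequencies within [lo, hi] inclusive."""
    idx = band_indices(np.asarray(freqs, dtype=float), band)
    return np.take(values, idx, axis=axis).mean(axis=axis)
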