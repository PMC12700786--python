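"""Phase-synchronisation index (PSI) between LFP and EEG/source channels.

The PSI of a channel pair at a frequency is the phase-locking value: the
modulus of the mean unit phasor of the phase difference, averaged over
trials and over the valid samples within each trial,

    PSI = | mean_{trials, samples} exp(i (phi_a - phi_b)) |,

with phases taken from the Morlet coefficients.  PSI is 1 for perfect
locking, and for N independent trials of uncoupled signals concentrates
around (sqrt(pi)/2)/sqrt(N) (the expected resultant length of N random unit
phasors).

Surrogate nulls destroy the trial pairing: each iteration permutes the
trial assignment of stream A relative to stream B (non-identity
permutations only) and recomputes the PSI, preserving within-trial spectral
structure and trial count.  Sliding-window PSI uses a short centred window
stepped along the epoch, band-averaged after the per-frequency PSI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import BandSpec, TFDecomposition, band_indices


@dataclass
class PSISeries:
    """PSI values for channel pairs, per frequency (static) or time (sliding)."""

    values: np.ndarray                 # (n_pairs, n_freqs) or (n_pairs, n_times)
    pairs: list[tuple[str, str]]
    n_trials: int
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None    # sliding-window centers, s
    band: str | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class SurrogateEnsemble:
    values: np.ndarray                 # (n_iter, n_pairs, n_freqs)
    pairs: list[tuple[str, str]]
    n_trials: int
    freqs: np.ndarray
    seed: int | None = None

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


def _unit_cross(tf_a: TFDecomposition, tf_b: TFDecomposition,
                idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Unit cross-phasors exp(i(phi_a - phi_b)): (trials, pairs, freqs, samples)."""
    if tf_a.n_trials != tf_b.n_trials:
        raise ValueError("mismatched trial counts")
    ca = tf_a.coeffs[:, idx_a]
    cb = tf_b.coeffs[:, idx_b]
    z = ca * np.conj(cb)
    mag = np.abs(z)
    if np.any(mag == 0):
        raise ValueError("zero-amplitude coefficient: phase undefined")
    return z / mag


def _resolve_pairs(tf_a, tf_b, pairs):
    if pairs is None:
        pairs = [(a, b) for a in tf_a.channel_labels for b in tf_b.channel_labels]
    idx_a = np.array([tf_a.channel_index(a) for a, _ in pairs])
    idx_b = np.array([tf_b.channel_index(b) for _, b in pairs])
    return pairs, idx_a, idx_b


def psi_static(tf_a: TFDecomposition, tf_b: TFDecomposition,
               pairs: list[tuple[str, str]] | None = None) -> PSISeries:
    """Static PSI per channel pair and frequency over valid samples."""
    pairs, idx_a, idx_b = _resolve_pairs(tf_a, tf_b, pairs)
    if tf_a.n_trials < 2:
        raise ValueError("PSI needs at least 2 trials")
    z = _unit_cross(tf_a, tf_b, idx_a, idx_b)
    valid = tf_a.valid & tf_b.valid
    w = valid[None, None, :, :]
    mean_z = (z * w).sum(axis=(0, 3)) / (tf_a.n_trials * valid.sum(axis=1))[None, :]
    return PSISeries(np.abs(mean_z), pairs, tf_a.n_trials,
                     freqs=tf_a.freqs.copy())


def surrogate_psi(tf_a: TFDecomposition, tf_b: TFDecomposition,
                  pairs: list[tuple[str, str]] | None = None,
                  n_iter: int = 100,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None) -> SurrogateEnsemble:
    """Trial-shuffled surrogate PSI ensemble.

    Each iteration applies a random non-identity permutation to stream A's
    trial order before the PSI computation; the ensemble mean estimates the
    chance-level PSI at the same trial count.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pairs, idx_a, idx_b = _resolve_pairs(tf_a, tf_b, pairs)
    n = tf_a.n_trials
    if n < 3:
        raise ValueError("surrogates need at least 3 trials for non-identity "
                         "permutations with unchanged marginals")
    ca = tf_a.coeffs[:, idx_a]
    cb = tf_b.coeffs[:, idx_b]
    if np.any(ca == 0) or np.any(cb == 0):
        raise ValueError("zero-amplitude coefficient: phase undefined")
    ua = np.ascontiguousarray(np.transpose(ca / np.abs(ca), (1, 2, 0, 3)))
    ub = np.transpose(cb / np.abs(cb), (1, 2, 0, 3))
    valid = tf_a.valid & tf_b.valid
    counts = valid.sum(axis=1)                       # per freq
    ub = np.ascontiguousarray(ub * valid[None, :, None, :])
    # cross-pairing sample sums S[p, f, i, j] = sum_s ua[i] conj(ub[j]);
    # a trial permutation's PSI is then a cheap diagonal gather
    S = ua @ np.conj(ub).swapaxes(-1, -2)
    out = np.empty((n_iter, len(pairs), tf_a.freqs.size))
    diag = np.arange(n)
    for k in range(n_iter):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, diag):
                break
        tot = S[:, :, perm, diag].sum(axis=-1)
        out[k] = np.abs(tot) / (n * counts)[None, :]
    return SurrogateEnsemble(out, pairs, n, tf_a.freqs.copy(), seed=seed)


def psi_with_surrogate(tf_a: TFDecomposition, tf_b: TFDecomposition,
                       n_iter: int = 100,
                       rng: np.random.Generator | None = None,
                       freq_mask: np.ndarray | None = None
                       ) -> tuple[PSISeries, SurrogateEnsemble]:
    """Static PSI and surrogate ensemble for every channel pair of a, b.

    Both quantities are read off one cross-pairing matrix
    ``S[i, j] = sum_s ua_i conj(ub_j)`` per pair and frequency: the static
    PSI is its diagonal sum, each surrogate iteration a permuted diagonal
    gather.  ``freq_mask`` restricts the frequency grid (e.g. to the band
    range) to save work.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if tf_a.n_trials != tf_b.n_trials:
        raise ValueError("mismatched trial counts")
    n = tf_a.n_trials
    if n < 3:
        raise ValueError("surrogates need at least 3 trials")
    fsel = np.flatnonzero(freq_mask) if freq_mask is not None \
        else np.arange(tf_a.freqs.size)
    freqs = tf_a.freqs[fsel]
    ca = tf_a.coeffs[:, :, fsel]
    cb = tf_b.coeffs[:, :, fsel]
    ua = ca / np.abs(ca)
    ub = cb / np.abs(cb)
    valid = (tf_a.valid & tf_b.valid)[fsel]
    counts = valid.sum(axis=1)
    ub = ub * valid[None, None, :, :]
    na, nb = ua.shape[1], ub.shape[1]
    pairs = [(a, b) for a in tf_a.channel_labels for b in tf_b.channel_labels]
    static = np.empty((na * nb, freqs.size))
    sur = np.empty((n_iter, na * nb, freqs.size))
    diag = np.arange(n)
    perms = []
    for _ in range(n_iter):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, diag):
                break
        perms.append(perm)
    for ia in range(na):
        A = np.ascontiguousarray(np.transpose(ua[:, ia], (1, 0, 2)))
        for ib in range(nb):
            B = np.transpose(ub[:, ib], (1, 0, 2))
            S = A @ np.conj(B).swapaxes(-1, -2)          # (freqs, i, j)
            row = ia * nb + ib
            static[row] = np.abs(S[:, diag, diag].sum(axis=-1)) / (n * counts)
            for k, perm in enumerate(perms):
                sur[k, row] = np.abs(S[:, perm, diag].sum(axis=-1)) / (n * counts)
    return (PSISeries(static, pairs, n, freqs=freqs),
            SurrogateEnsemble(sur, pairs, n, freqs))


def sliding_centers(t_start: float, t_stop: float, step: float) -> np.ndarray:
    """Inclusive center grid, e.g. -1.8..0 at 0.004 s -> 451 points."""
    n = int(round((t_stop - t_start) / step)) + 1
    return t_start + step * np.arange(n)


def psi_sliding(tf_a: TFDecomposition, tf_b: TFDecomposition,
                band: BandSpec,
                pairs: list[tuple[str, str]] | None = None,
                window: float = 0.3, step: float = 0.004,
                t_range: tuple[float, float] = (-1.8, 0.6)) -> PSISeries:
    """Sliding-window PSI, band-averaged (PSI per frequency, then band mean).

    At each center t on the step grid the PSI pools samples in
    [t - window/2, t + window/2] across trials.  Centers whose window falls
    outside the epoch raise.
    """
    pairs, idx_a, idx_b = _resolve_pairs(tf_a, tf_b, pairs)
    z = _unit_cross(tf_a, tf_b, idx_a, idx_b)
    fidx = band_indices(tf_a.freqs, band)
    z = z[:, :, fidx, :]
    rate = tf_a.rate
    w = int(round(window * rate))
    centers = sliding_centers(t_range[0], t_range[1], step)
    c_idx = np.round((centers - tf_a.times[0]) * rate).astype(int)
    starts = c_idx - w // 2
    if starts.min() < 0 or (starts + w).max() > z.shape[-1]:
        raise ValueError("sliding window exceeds epoch bounds; pad the epochs")
    # windowed sums via cumulative sums along samples
    csum = np.cumsum(z, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    win_sums = csum[..., starts + w] - csum[..., starts]   # trials,pairs,f,centers
    psi_f = np.abs(win_sums.sum(axis=0)) / (z.shape[0] * w)
    values = psi_f.mean(axis=1)                            # pairs x centers
    return PSISeries(values, pairs, z.shape[0], times=centers, band=band.name,
                     meta={"window_s": window, "step_s": step})


def power_sliding(tf: TFDecomposition, band: BandSpec, channels=None,
                  window: float = 0.3, step: float = 0.004,
                  t_range: tuple[float, float] = (-1.8, 0.6)) -> PSISeries:
    """Sliding-window band power (trial mean), same grid as psi_sliding."""
    labels = channels or tf.channel_labels
    idx = np.array([tf.channel_index(c) for c in labels])
    fidx = band_indices(tf.freqs, band)
    p = np.abs(tf.coeffs[:, idx][:, :, fidx, :]) ** 2
    rate = tf.rate
    w = int(round(window * rate))
    centers = sliding_centers(t_range[0], t_range[1], step)
    starts = np.round((centers - tf.times[0]) * rate).astype(int) - w // 2
    if starts.min() < 0 or (starts + w).max() > p.shape[-1]:
        raise ValueError("sliding window exceeds epoch bounds; pad the epochs")
    csum = np.cumsum(p, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    win_means = (csum[..., starts + w] - csum[..., starts]) / w
    values = win_means.mean(axis=(0, 2))                   # channels x centers
    return PSISeries(values, [(c, "") for c in labels], p.shape[0],
                     times=centers, band=band.name,
                     meta={"window_s": window, "step_s": step, "quantity": "power"})


def relative_change(values: np.ndarray, baseline) -> np.ndarray:
    """Fractional change (value - baseline) / baseline, e.g. tic vs rest."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be positive")
    return (np.asarray(values, dtype=float) - baseline[..., None]) / baseline[..., None]
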