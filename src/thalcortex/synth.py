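"""Synthetic cohorts with known ground truth for parameter-recovery tests.

The generator emulates the statistical structure the analysis assumes: a
band-limited thalamic alpha oscillator (phase random walk inside 8-12 Hz)
recorded as bipolar LFP at 250 Hz, and EEG channels that carry the same
oscillation with a von Mises phase jitter of concentration kappa around the
LFP phase, on top of 1/f background noise.  The von Mises model gives a
closed-form expected phase-locking value,

    E[PLV] = I1(kappa) / I0(kappa),

which serves as the analytic oracle for the connectivity estimators
(kappa = 0: no coupling, chance-level PSI; kappa -> inf: PLV -> 1).

Tic events obey the analysis' own selection rules (inter-tic gaps large
enough that the >= 2 s isolation rule holds after merging).  In a window
[ramp_start, 0] before each tic onset the coupled oscillation is gradually
cross-faded into an independent oscillator, removing up to ``ramp_depth`` of
the coupling at onset — the programmed pre-tic decoupling the event-locked
analysis should recover.  Clinical severity scores decrease monotonically
with coupling strength, so the pipeline should recover a negative
PSI-severity rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .io_formats import (ClinicalRecord, EventTable, Modality, Recording)

# 63-channel extended 10-20 montage (online reference Cz excluded)
EEG_CHANNELS_63 = [
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]

# channels over which the thalamo-cortical coupling is concentrated
FRONTAL_PRESET = ("Fz", "F1", "F2", "F3", "F4", "FC1", "FC2", "AFz")

LFP_CHANNELS = ["lfp_left", "lfp_right"]


def expected_plv(kappa: float) -> float:
    """Closed-form expected phase-locking value of von Mises phase jitter."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_plv(plv: float) -> float:
    """Inverse of :func:`expected_plv` (numeric)."""
    if not 0 <= plv < 1:
        raise ValueError("PLV must lie in [0, 1)")
    if plv == 0:
        return 0.0
    return float(brentq(lambda k: expected_plv(k) - plv, 1e-9, 1e4))


@dataclass
class GroundTruth:
    """Generator parameters for one synthetic patient.

    ``kappa`` maps EEG channel name -> von Mises concentration of that
    channel's phase coupling to the LFP alpha oscillator (channels absent
    from the map are uncoupled).  ``ramp_start`` (s, negative) and
    ``ramp_depth`` (fraction of coupling removed at tic onset) define the
    pre-tic decoupling ramp.  Amplitudes are in µV.
    """

    kappa: dict[str, float] = field(default_factory=dict)
    band_center: float = 10.0
    band_width: float = 4.0
    ramp_start: float = -0.3
    ramp_depth: float = 0.8
    osc_amp_lfp: float = 3.0
    osc_amp_eeg: float = 10.0
    noise_amp_lfp: float = 2.0
    noise_amp_eeg: float = 5.0
    # independent theta / low-beta background rhythms (per stream and
    # channel).  Real recordings carry such rhythms; they dominate the
    # phases of the neighbouring bands so that coupling stays confined to
    # alpha even though the wavelet's spectral skirt reaches past 12 Hz.
    # Scaled relative to the stream's oscillation amplitude.
    mask_rel_theta: float = 0.0
    mask_rel_beta: float = 0.0
    lfp_clock_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(k < 0 for k in self.kappa.values()):
            raise ValueError("kappa must be non-negative")
        if not -2.0 <= self.ramp_start < 0:
            raise ValueError("ramp_start must lie in [-2, 0)")
        if not 0 <= self.ramp_depth <= 1:
            raise ValueError("ramp_depth must lie in [0, 1]")


@dataclass
class Session:
    """One streaming block: paired LFP + EEG recordings and their events.

    ``source`` optionally carries reconstructed cortical ROI time series
    (SOURCE modality, analysis rate); iterating a Session yields
    ``(lfp, eeg, events)`` for convenience.
    """

    lfp: Recording
    eeg: Recording
    events: EventTable
    source: Recording | None = None

    def __iter__(self):
        return iter((self.lfp, self.eeg, self.events))


@dataclass
class PatientData:
    patient_id: str
    sessions: dict[str, Session]        # condition -> Session
    clinical: ClinicalRecord
    truth: GroundTruth


@dataclass
class Cohort:
    patients: list[PatientData]
    seed: int

    @property
    def clinical(self) -> list[ClinicalRecord]:
        return [p.clinical for p in self.patients]


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (power) noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _bandpass_noise(n: int, rate: float, lo: float, hi: float,
                    rng: np.random.Generator, roll: float = 1.0) -> np.ndarray:
    """Unit-variance noise band-limited to [lo, hi] Hz with cosine edges."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    gain = np.zeros_like(f)
    gain[(f >= lo) & (f <= hi)] = 1.0
    rise = (f >= lo - roll) & (f < lo)
    gain[rise] = 0.5 - 0.5 * np.cos(np.pi * (f[rise] - lo + roll) / roll)
    fall = (f > hi) & (f <= hi + roll)
    gain[fall] = 0.5 + 0.5 * np.cos(np.pi * (f[fall] - hi) / roll)
    x = np.fft.irfft(spec * gain, n)
    return x / x.std()


def _master_phase(n: int, rate: float, center: float, width: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unwrapped phase of a narrowband oscillator wandering inside the band."""
    from scipy.signal import fftconvolve

    steps = rng.standard_normal(n)
    # smooth the frequency track over ~1 s so the wander stays narrowband
    k = int(rate)
    kernel = np.hanning(k)
    kernel /= kernel.sum()
    track = fftconvolve(steps, kernel, mode="same")
    sd = track.std() or 1.0
    f_inst = center + 0.5 * width * np.clip(track / (2 * sd), -1.0, 1.0)
    return 2 * np.pi * np.cumsum(f_inst) / rate


def _jitter_track(n: int, rate: float, kappa: float,
                  rng: np.random.Generator, segment_s: float = 2.0,
                  blend_s: float = 0.1) -> np.ndarray:
    """Piecewise-constant von Mises phase jitter with short smooth blends.

    The jitter is resampled independently every ``segment_s`` seconds so
    that epochs are (approximately) independent draws from the von Mises
    marginal; boundaries are cross-faded over ``blend_s`` along the shortest
    angular path.
    """
    seg = max(int(round(segment_s * rate)), 1)
    n_seg = int(np.ceil(n / seg))
    draws = rng.vonmises(0.0, kappa, size=n_seg) if kappa > 0 \
        else rng.uniform(-np.pi, np.pi, size=n_seg)
    theta = np.repeat(draws, seg)[:n]
    nb = max(int(round(blend_s * rate)), 1)
    ramp = 0.5 - 0.5 * np.cos(np.linspace(0, np.pi, nb))
    for b in range(1, n_seg):
        i = b * seg
        if i >= n:
            break
        prev, cur = draws[b - 1], draws[b]
        step = np.angle(np.exp(1j * (cur - prev)))
        j = min(nb, n - i)
        theta[i:i + j] = prev + step * ramp[:j]
    return theta


def _tic_times(duration: float, rng: np.random.Generator,
               mean_interval: float = 7.0) -> list[tuple[float, float]]:
    """Tic (onset, offset) pairs with gaps that keep every tic isolated."""
    out = []
    t = 4.0 + rng.uniform(0.0, 2.0)
    while True:
        dur = rng.uniform(0.3, 0.8)
        if t + dur > duration - 2.0:
            break
        out.append((t, t + dur))
        t = t + dur + rng.uniform(mean_interval - 2.0, mean_interval + 2.0)
    return out


def _ramp_profile(times: np.ndarray, tics: list[tuple[float, float]],
                  ramp_start: float, depth: float,
                  recover_s: float = 0.3) -> np.ndarray:
    """Mixing weight m(t): 0 = fully coupled, rising to ``depth`` at onset."""
    m = np.zeros_like(times)
    for onset, _ in tics:
        t0 = onset + ramp_start
        up = (times >= t0) & (times < onset)
        m[up] = np.maximum(m[up], depth * (times[up] - t0) / (-ramp_start))
        down = (times >= onset) & (times < onset + recover_s)
        m[down] = np.maximum(m[down], depth * (1 - (times[down] - onset) / recover_s))
    return m


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_recording(duration: float, truth: GroundTruth,
                       lfp_rate: float = 250.0, eeg_rate: float = 5000.0,
                       eeg_channels: list[str] | None = None,
                       condition: str = "tic_freely",
                       with_tics: bool = True,
                       seed: int | None = None,
                       kappa_scale: float = 1.0,
                       source_channels: list[str] | None = None) -> Session:
    """Generate one session of paired LFP + EEG (+ optional source) streams.

    Both streams observe the same alpha oscillator; EEG channel phases
    carry von Mises(0, kappa_c) jitter.  Tic events (if any) imprint the
    pre-onset decoupling ramp on every coupled EEG channel.  Sync markers
    are written near the start and end of both streams; the LFP stream's
    own clock is shifted by ``truth.lfp_clock_offset``.  When
    ``source_channels`` are named, reconstructed-source ROI time series are
    emitted at the LFP rate, coupled through the same kappa map.
    Deterministic under the seed.
    """
    if duration < 10:
        raise ValueError("duration must allow at least one 4 s epoch plus margins")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    channels = list(eeg_channels) if eeg_channels is not None else list(EEG_CHANNELS_63)

    n_lfp = int(round(duration * lfp_rate))
    n_eeg = int(round(duration * eeg_rate))
    t_lfp = np.arange(n_lfp) / lfp_rate
    t_eeg = np.arange(n_eeg) / eeg_rate

    phi = _master_phase(n_lfp, lfp_rate, truth.band_center, truth.band_width, rng)
    phi_eeg = np.interp(t_eeg, t_lfp, phi)
    # independent oscillator the coupled channels decouple into during ramps
    psi = _master_phase(n_lfp, lfp_rate, truth.band_center, truth.band_width, rng)
    psi_eeg = np.interp(t_eeg, t_lfp, psi)

    tics = _tic_times(duration, rng) if with_tics else []
    m = _ramp_profile(t_eeg, tics, truth.ramp_start, truth.ramp_depth) \
        if tics and truth.ramp_depth > 0 else np.zeros(n_eeg)

    def background(n, rate, osc_amp, noise_amp):
        x = noise_amp * _pink_noise(n, rng)
        if truth.mask_rel_theta > 0:
            x += truth.mask_rel_theta * osc_amp * _bandpass_noise(
                n, rate, 3.0, 7.5, rng)
        if truth.mask_rel_beta > 0:
            x += truth.mask_rel_beta * osc_amp * _bandpass_noise(
                n, rate, 12.5, 19.0, rng)
        return x

    lfp = np.empty((2, n_lfp))
    for i in range(2):
        lfp[i] = truth.osc_amp_lfp * np.cos(phi) \
            + background(n_lfp, lfp_rate, truth.osc_amp_lfp,
                         truth.noise_amp_lfp)

    def coupled_channel(ch, n, rate, t, phi_t, psi_t, mix):
        kappa = truth.kappa.get(ch, 0.0) * kappa_scale
        if kappa <= 0:
            # an uncoupled cortical alpha source is its own oscillator whose
            # phase drifts freely against the thalamic one
            phi_own = np.interp(t, t_lfp, _master_phase(
                n_lfp, lfp_rate, truth.band_center, truth.band_width, rng))
            osc = np.cos(phi_own)
        else:
            theta = _jitter_track(n, rate, kappa, rng)
            osc = np.cos(phi_t + theta)
            if mix.any():
                osc = np.sqrt(1 - mix) * osc + np.sqrt(mix) * np.cos(psi_t + theta)
        return truth.osc_amp_eeg * osc \
            + background(n, rate, truth.osc_amp_eeg, truth.noise_amp_eeg)

    eeg = np.empty((len(channels), n_eeg))
    for ci, ch in enumerate(channels):
        eeg[ci] = coupled_channel(ch, n_eeg, eeg_rate, t_eeg, phi_eeg, psi_eeg, m)

    source = None
    if source_channels:
        m_lfp = _ramp_profile(t_lfp, tics, truth.ramp_start, truth.ramp_depth) \
            if tics and truth.ramp_depth > 0 else np.zeros(n_lfp)
        src = np.empty((len(source_channels), n_lfp))
        for ci, ch in enumerate(source_channels):
            src[ci] = coupled_channel(ch, n_lfp, lfp_rate, t_lfp, phi, psi, m_lfp)
        source = Recording(src, lfp_rate, list(source_channels),
                           Modality.SOURCE)

    rows = [{"onset": on, "offset": off, "kind": "tic",
             "tic_type": rng.choice(["simple motor", "simple vocal",
                                     "complex motor"]),
             "condition": condition} for on, off in tics]
    for t0 in (0.5, duration - 0.5):
        rows.append({"onset": t0 - 0.1, "offset": t0 + 0.1,
                     "kind": "artifact_sync", "tic_type": "", "condition": ""})
    events = EventTable.from_records(rows)

    c = truth.lfp_clock_offset
    lfp_rec = Recording(lfp, lfp_rate, list(LFP_CHANNELS), Modality.LFP,
                        start_offset=c,
                        meta={"hemisphere": {"lfp_left": "left",
                                             "lfp_right": "right"},
                              "gaps": []})
    eeg_rec = Recording(eeg, eeg_rate, channels, Modality.EEG)
    return Session(lfp_rec, eeg_rec, events, source)


def lfp_events(events: EventTable, truth: GroundTruth) -> EventTable:
    """The session events re-stamped on the LFP stream's own clock."""
    return events.shifted(truth.lfp_clock_offset)


def generate_cohort(n_patients: int = 6,
                    kappa_range: tuple[float, float] = (2.0, 30.0),
                    clinical_noise_sd: float = 2.0,
                    seed: int = 0,
                    durations: dict[str, float] | None = None,
                    eeg_channels: list[str] | None = None,
                    eeg_rate: float = 5000.0,
                    frontal: tuple[str, ...] = FRONTAL_PRESET,
                    suppression_kappa_scale: float = 1.0,
                    ramp_depth: float = 0.8,
                    ramp_start: float = -0.3,
                    source_rois: tuple[str, ...] | None = None,
                    source_kappa: float | None = None,
                    truth_overrides: dict | None = None) -> Cohort:
    """Generate a cohort with per-patient coupling and linked severity scores.

    Per-patient kappas are spaced over ``kappa_range`` so the expected PLVs
    are evenly separated (maximally rank-recoverable); the channel of
    maximal coupling is Fz, with the remaining frontal-preset channels at
    75% of the patient's kappa.  Severity scores decrease linearly in the
    expected PLV plus Gaussian noise, truncated at zero.

    Unlike the clean single-recording defaults, cohort recordings use a
    realistic signal regime: a weak alpha oscillation (below the broadband
    background, yielding sensor PSI values in the 0.2-0.4 range) and
    independent theta/low-beta background rhythms, so that coupling is
    measurable yet spectrally confined to the alpha band as in real
    recordings.  ``truth_overrides`` can replace any of these generator
    fields.
    """
    if n_patients < 2:
        raise ValueError("cohort needs at least 2 patients")
    lo, hi = kappa_range
    if not hi > lo >= 0:
        raise ValueError("degenerate kappa_range")
    durations = durations or {"rest": 420.0, "tic_freely": 900.0,
                              "tic_suppression": 900.0}
    rng = np.random.default_rng(seed)
    plv_targets = np.linspace(expected_plv(lo), expected_plv(hi), n_patients)
    kappas = [kappa_for_plv(p) for p in plv_targets]

    patients = []
    for i, kap in enumerate(kappas):
        kmap = {ch: (1.0 if ch == "Fz" else 0.75) * kap for ch in frontal}
        if source_rois:
            for roi in source_rois:
                kmap[roi] = source_kappa if source_kappa is not None else kap
        fields = dict(osc_amp_eeg=2.5, noise_amp_eeg=5.0,
                      osc_amp_lfp=1.0, noise_amp_lfp=2.0,
                      mask_rel_theta=2.0, mask_rel_beta=2.0)
        fields.update(truth_overrides or {})
        truth = GroundTruth(kappa=kmap, ramp_depth=ramp_depth,
                            ramp_start=ramp_start,
                            lfp_clock_offset=float(rng.uniform(1.0, 3.0)),
                            seed=int(rng.integers(0, 2 ** 31 - 1)), **fields)
        sessions = {}
        for cond, dur in durations.items():
            if dur <= 0:
                continue
            scale = suppression_kappa_scale if cond == "tic_suppression" else 1.0
            sessions[cond] = generate_recording(
                dur, truth, eeg_rate=eeg_rate, eeg_channels=eeg_channels,
                condition=cond, seed=int(rng.integers(0, 2 ** 31 - 1)),
                kappa_scale=scale, source_channels=list(source_rois or ()))
        plv = expected_plv(kap)
        tts = max(0.0, 60.0 - 50.0 * plv + clinical_noise_sd * rng.standard_normal())
        puts = max(0.0, 70.0 - 45.0 * plv + clinical_noise_sd * rng.standard_normal())
        clinical = ClinicalRecord(
            patient_id=f"P{i + 1:02d}", ygtss_tts=tts, ygtss_global=tts + 18.0,
            puts=puts, months_since_op=float(rng.integers(3, 165)),
            dbs_target="CM_Voi" if rng.random() < 0.8 else "VA_VL",
            ipg_side="left" if rng.random() < 0.5 else "right")
        patients.append(PatientData(clinical.patient_id, sessions, clinical, truth))
    return Cohort(patients, seed)


def ground_truth_report(cohort: Cohort) -> pd.DataFrame:
    """Tabulate each patient's coupling parameters and expected PLVs."""
    rows = []
    for p in cohort.patients:
        for ch, kap in sorted(p.truth.kappa.items()):
            rows.append({"patient": p.patient_id, "channel": ch,
                         "kappa": kap, "expected_plv": expected_plv(kap),
                         "ramp_start": p.truth.ramp_start,
                         "ramp_depth": p.truth.ramp_depth})
    return pd.DataFrame(rows)


def truth_to_json(truth: GroundTruth) -> dict:
    return asdict(truth)
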