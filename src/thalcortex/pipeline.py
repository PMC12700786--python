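"""Orchestration of the three analyses: rest, suppression, and tic-locked.

Units of analysis follow the study design: each implanted thalamus
(hemisphere) is one independent sample for group t-tests and ANOVA, while
clinical correlations are computed per patient on hemisphere-averaged
values.

Rest analysis
    Band-averaged LFP-EEG PSI per hemisphere and channel, original vs
    trial-shuffled surrogate, enters a per-channel 2x3x2 permutation ANOVA
    (Condition x Frequency x Hemisphere).  Channels with a
    Condition-by-Frequency interaction whose post-hoc original-vs-surrogate
    difference is confined to the alpha band are flagged (FDR over the whole
    family of channel and post-hoc p-values).  The alpha-peak channel is
    tested against the mean of all other channels, and hemisphere-averaged
    alpha PSI at the channel of interest is rank-correlated with severity
    scores (thalamic and frontal alpha power serve as specificity controls).

Suppression analysis
    Paired permutation t-tests comparing tic-freely vs tic-suppression on
    tic rate, alpha PSI at the channel of interest, LFP alpha power and
    frontal alpha power.

Tic analysis
    Tic epochs pooled over conditions; sliding-window alpha PSI (0.3 s
    window, 4 ms steps) against a trial-count-matched rest baseline,
    aggregated into 100-ms test windows stepped by 20 ms over -1.8..0.6 s,
    per-window paired permutation t-tests, cluster-size Monte-Carlo
    correction, and a linear time trend over the pre-onset range.  The same
    machinery runs on LFP/frontal power and, when reconstructed source ROI
    time series are supplied, on thalamo-ROI PSI and ROI power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (psi_sliding, psi_static, power_sliding,
                           psi_with_surrogate, relative_change,
                           sliding_centers)
from .epochs import (EpochSet, extract_epochs_at, extract_tic_epochs,
                     merge_tic_sequences, pool_conditions,
                     rest_segment_starts, resample_recording,
                     select_isolated_tics)
from .io_formats import ClinicalRecord, synchronize_streams
from .spectral import (BANDS, BandSpec, band_average, decompose,
                       normalize_power, power_spectrum)
from .stats import (ClusterResult, StatResult, StatsConfig, TrendResult,
                    cluster_mcs, fdr_bh, linreg_trend, perm_anova,
                    perm_posthoc, perm_spearman, perm_ttest_paired)

DEFAULT_ROIS = ("M1", "S1", "CMC", "SMA", "PMC", "IC/FOp", "ACC/mPFC", "IPC")


@dataclass
class AnalysisConfig:
    """Defaults mirror the study's analysis settings."""

    bands: tuple[BandSpec, ...] = BANDS
    rest_epoch_s: float = 4.0
    tic_window: tuple[float, float] = (-2.1, 0.9)   # cut window, padded
    tic_range: tuple[float, float] = (-1.8, 0.6)    # analysis range
    test_window: float = 0.1
    test_step: float = 0.02
    slide_window: float = 0.3
    slide_step: float = 0.004
    channel_of_interest: str = "Fz"
    roi_labels: tuple[str, ...] = DEFAULT_ROIS
    analysis_rate: float = 250.0
    surrogate_iters: int = 100
    baseline_bootstraps: int = 50
    eeg_chunk: int = 4                              # channels decomposed at once
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self):
        if self.test_window <= self.test_step:
            raise ValueError("test_window must exceed test_step")
        lo, hi = self.tic_range
        if lo - self.slide_window / 2 < self.tic_window[0] \
                or hi + self.slide_window / 2 > self.tic_window[1]:
            raise ValueError("tic_range plus half a sliding window must fit "
                             "inside the cut window")

    def band(self, name: str) -> BandSpec:
        return next(b for b in self.bands if b.name == name)


# ---------------------------------------------------------------------------
# epoch preparation
# ---------------------------------------------------------------------------

def _session_sync(session) -> "SyncModel":
    lfp_ev = session.events.shifted(
        session.lfp.start_offset).of_kind("artifact_sync")
    return synchronize_streams(lfp_ev, session.events.of_kind("artifact_sync"))


def prepare_rest_epochs(session, cfg: AnalysisConfig,
                        condition: str = "tic_freely"):
    """Sample-aligned (LFP, EEG[, source]) rest epoch sets for one session."""
    sync = _session_sync(session)
    events = select_isolated_tics(merge_tic_sequences(session.events))
    eeg = resample_recording(session.eeg, cfg.analysis_rate)
    starts = rest_segment_starts(events, session.eeg.duration, cfg.rest_epoch_s)
    if starts.size == 0:
        raise ValueError("no rest segment available outside events")
    window = (0.0, cfg.rest_epoch_s)
    ep_eeg = extract_epochs_at(eeg, starts, window, condition=condition)
    ep_lfp = extract_epochs_at(session.lfp, starts, window,
                               time_map=sync.b_to_a, condition=condition)
    keep = min(ep_eeg.n_trials, ep_lfp.n_trials)
    out = [_truncate(ep_lfp, keep), _truncate(ep_eeg, keep)]
    if session.source is not None:
        out.append(_truncate(extract_epochs_at(session.source, starts, window,
                                               condition=condition), keep))
    else:
        out.append(None)
    return tuple(out)


def prepare_tic_epochs(session, cfg: AnalysisConfig):
    """Sample-aligned (LFP, EEG[, source]) tic epoch sets for one session."""
    sync = _session_sync(session)
    events = select_isolated_tics(merge_tic_sequences(session.events))
    if len(events.tics()) == 0:
        return None
    eeg = resample_recording(session.eeg, cfg.analysis_rate)
    cond = events.tics().df["condition"].iloc[0]
    ep_eeg = extract_tic_epochs(eeg, events, cfg.tic_window, condition=None)
    ep_eeg.condition = cond
    ep_lfp = extract_epochs_at(session.lfp, ep_eeg.trial_meta["onset"].to_numpy(),
                               cfg.tic_window, time_map=sync.b_to_a,
                               anchor="tic_onset", condition=cond)
    keep = min(ep_eeg.n_trials, ep_lfp.n_trials)
    out = [_truncate(ep_lfp, keep), _truncate(ep_eeg, keep)]
    if session.source is not None:
        out.append(_truncate(
            extract_epochs_at(session.source,
                              ep_eeg.trial_meta["onset"].to_numpy()[:keep],
                              cfg.tic_window, anchor="tic_onset",
                              condition=cond), keep))
    else:
        out.append(None)
    return tuple(out)


def _truncate(ep: EpochSet, n: int) -> EpochSet:
    if ep.n_trials == n:
        return ep
    return EpochSet(ep.data[:n], ep.rate, ep.window, ep.anchor,
                    list(ep.channel_labels), ep.condition,
                    ep.trial_meta.iloc[:n].reset_index(drop=True), dict(ep.meta))


def pooled_epochs(patient, cfg, conditions, kind: str) -> dict:
    """Pool each stream's epoch sets across a patient's sessions.

    Returns ``{"lfp": EpochSet, "eeg": EpochSet, "source": EpochSet | None}``;
    raises if no session yields any epoch of the requested kind.
    """
    per_stream = {"lfp": [], "eeg": [], "source": []}
    for cond in conditions:
        if cond not in patient.sessions:
            continue
        try:
            prep = prepare_rest_epochs(patient.sessions[cond], cfg, cond) \
                if kind == "rest" \
                else prepare_tic_epochs(patient.sessions[cond], cfg)
        except ValueError:
            continue
        if prep is None:
            continue
        for key, ep in zip(("lfp", "eeg", "source"), prep):
            if ep is not None:
                per_stream[key].append(ep)
    if not per_stream["lfp"]:
        raise ValueError(f"patient {patient.patient_id}: no {kind} epochs")
    return {k: pool_conditions(*v) if v else None
            for k, v in per_stream.items()}


# ---------------------------------------------------------------------------
# rest features
# ---------------------------------------------------------------------------

@dataclass
class RestFeatures:
    """Band-averaged PSI and power per hemisphere, original and surrogate."""

    patient_ids: list[str]              # one entry per hemisphere row
    hemispheres: list[str]
    channels: list[str]
    band_names: list[str]
    psi_orig: np.ndarray                # hemis x channels x bands
    psi_surr: np.ndarray
    lfp_power: np.ndarray               # hemis x bands (normalised %)
    eeg_power: dict                     # patient -> channels x bands
    n_trials: dict                      # patient -> trial count


def compute_rest_features(patients, cfg: AnalysisConfig,
                          conditions=("rest", "tic_freely"),
                          rng: np.random.Generator | None = None,
                          stream: str = "eeg") -> RestFeatures:
    """PSI/surrogate/power features from pooled rest epochs per patient.

    EEG channels are decomposed in chunks to bound memory at high channel
    counts; the surrogate ensemble uses ``cfg.surrogate_iters`` trial-pairing
    permutations.
    """
    rng = rng if rng is not None else cfg.stats.rng()
    rows_pid, rows_hemi = [], []
    psi_o, psi_s, lfp_pow = [], [], []
    eeg_power, n_trials = {}, {}
    channels = None
    for patient in patients:
        pooled = pooled_epochs(patient, cfg, conditions, "rest")
        ep_lfp, ep_tgt = pooled["lfp"], pooled[stream]
        if ep_tgt is None:
            raise ValueError(f"patient {patient.patient_id}: "
                             f"no {stream} rest epochs")
        if channels is None:
            channels = list(ep_tgt.channel_labels)
        tf_lfp = decompose(ep_lfp)
        ps_lfp = normalize_power(power_spectrum(tf_lfp))
        n_trials[patient.patient_id] = ep_lfp.n_trials
        n_ch, n_b = len(channels), len(cfg.bands)
        orig = np.zeros((2, n_ch, n_b))
        surr = np.zeros((2, n_ch, n_b))
        pw = np.zeros((n_ch, n_b))
        lo = min(b.lo for b in cfg.bands)
        hi = max(b.hi for b in cfg.bands)
        fmask = (tf_lfp.freqs >= lo) & (tf_lfp.freqs <= hi)
        for c0 in range(0, n_ch, cfg.eeg_chunk):
            chunk = channels[c0:c0 + cfg.eeg_chunk]
            tf_c = decompose(ep_tgt.pick(chunk))
            ps_c = normalize_power(power_spectrum(tf_c))
            st, su = psi_with_surrogate(tf_lfp, tf_c,
                                        n_iter=cfg.surrogate_iters, rng=rng,
                                        freq_mask=fmask)
            su_mean = su.mean
            for h in range(len(ep_lfp.channel_labels)):
                rows = slice(h * len(chunk), (h + 1) * len(chunk))
                for bi, band in enumerate(cfg.bands):
                    orig[h, c0:c0 + len(chunk), bi] = band_average(
                        st.values[rows], st.freqs, band)
                    surr[h, c0:c0 + len(chunk), bi] = band_average(
                        su_mean[rows], su.freqs, band)
            for bi, band in enumerate(cfg.bands):
                pw[c0:c0 + len(chunk), bi] = band_average(
                    ps_c.values, ps_c.freqs, band)
        eeg_power[patient.patient_id] = pw
        for h, lfp_ch in enumerate(ep_lfp.channel_labels):
            hemi = lfp_ch.split("_")[-1]
            rows_pid.append(patient.patient_id)
            rows_hemi.append(hemi)
            psi_o.append(orig[h])
            psi_s.append(surr[h])
            lfp_pow.append([band_average(ps_lfp.values[h], ps_lfp.freqs, b)
                            for b in cfg.bands])
    return RestFeatures(rows_pid, rows_hemi, channels,
                        [b.name for b in cfg.bands],
                        np.array(psi_o), np.array(psi_s),
                        np.array(lfp_pow), eeg_power, n_trials)


# ---------------------------------------------------------------------------
# rest analysis
# ---------------------------------------------------------------------------

@dataclass
class RestAnalysisResult:
    anova: dict                          # channel -> {term: StatResult}
    posthoc: dict                        # (channel, band) -> StatResult
    fdr_rejected: dict                   # label -> bool, over the whole family
    flagged_channels: list[str]
    peak_channel: str
    peak_psi_mean: float
    peak_psi_sem: float
    peak_test: StatResult
    correlations: dict                   # score -> CorrelationResult
    correlations_fdr: dict               # score -> bool
    control_correlations: dict           # ("lfp_power"|"chan_power", score) -> CorrelationResult
    channel_alpha_psi: pd.DataFrame


def run_rest_analysis(features: RestFeatures,
                      clinical: list[ClinicalRecord],
                      cfg: AnalysisConfig) -> RestAnalysisResult:
    if len(set(zip(features.patient_ids, features.hemispheres))) < 2:
        raise ValueError("rest analysis needs at least 2 hemisphere samples")
    rng = cfg.stats.rng()
    n_h = len(features.patient_ids)
    bands = features.band_names
    alpha_i = bands.index("alpha")
    cond = np.array(["orig", "surr"]).repeat(len(bands))
    cond_f = np.tile(cond, n_h)
    band_f = np.tile(np.tile(np.array(bands), 2), n_h)
    hemi_f = np.repeat(np.array(features.hemispheres), 2 * len(bands))

    anova, posthoc = {}, {}
    family_labels, family_p = [], []
    for ci, ch in enumerate(features.channels):
        y = np.concatenate([
            np.concatenate([features.psi_orig[h, ci], features.psi_surr[h, ci]])
            for h in range(n_h)])
        res = perm_anova(y, {"cond": cond_f, "freq": band_f, "hemi": hemi_f},
                         cfg.stats, rng=rng)
        anova[ch] = res
        family_labels.append(("interaction", ch))
        family_p.append(res[("cond", "freq")].p_mc)
        for bi, b in enumerate(bands):
            sel = band_f == b
            ph = perm_posthoc(y[sel], cond_f[sel], cfg.stats, rng=rng,
                              pairs=[("orig", "surr")])[0]
            posthoc[(ch, b)] = ph
            family_labels.append(("posthoc", ch, b))
            family_p.append(ph.p_mc)

    rejected, _ = fdr_bh(family_p, cfg.stats.fdr_alpha)
    fdr_rejected = dict(zip(family_labels, rejected.tolist()))
    flagged = []
    for ch in features.channels:
        if not fdr_rejected[("interaction", ch)]:
            continue
        alpha_sig = fdr_rejected[("posthoc", ch, "alpha")]
        others_sig = any(fdr_rejected[("posthoc", ch, b)]
                         for b in bands if b != "alpha")
        if alpha_sig and not others_sig:
            flagged.append(ch)

    # peak alpha channel vs mean of the others, paired over hemispheres
    alpha_psi = features.psi_orig[:, :, alpha_i]          # hemis x channels
    mean_by_channel = alpha_psi.mean(axis=0)
    peak_i = int(np.argmax(mean_by_channel))
    peak_channel = features.channels[peak_i]
    peak_vals = alpha_psi[:, peak_i]
    others = alpha_psi[:, [i for i in range(len(features.channels))
                           if i != peak_i]].mean(axis=1)
    peak_test = perm_ttest_paired(peak_vals, others, cfg.stats, rng=rng)
    peak_mean = float(peak_vals.mean())
    peak_sem = float(peak_vals.std(ddof=1) / np.sqrt(n_h))

    # clinical correlations on hemisphere-averaged alpha PSI at the channel
    # of interest; thalamic and frontal alpha power as specificity controls
    coi = cfg.channel_of_interest if cfg.channel_of_interest in features.channels \
        else peak_channel
    coi_i = features.channels.index(coi)
    by_patient = {}
    for h, pid in enumerate(features.patient_ids):
        by_patient.setdefault(pid, []).append(h)
    pids = list(by_patient)
    clin = {c.patient_id: c for c in clinical}
    missing = [p for p in pids if p not in clin]
    if missing:
        raise ValueError(f"missing clinical scores for patient(s) {missing}")
    psi_pat = np.array([alpha_psi[by_patient[p], coi_i].mean() for p in pids])
    lfp_pow_pat = np.array([features.lfp_power[by_patient[p], alpha_i].mean()
                            for p in pids])
    chan_pow_pat = np.array([features.eeg_power[p][coi_i, alpha_i] for p in pids])
    scores = {"ygtss_tts": np.array([clin[p].ygtss_tts for p in pids]),
              "puts": np.array([clin[p].puts for p in pids])}
    correlations, correlations_fdr, controls = {}, {}, {}
    if len(pids) >= 3:
        correlations = {s: perm_spearman(psi_pat, v, cfg.stats, rng=rng)
                        for s, v in scores.items()}
        corr_rej, _ = fdr_bh([correlations[s].p for s in scores],
                             cfg.stats.fdr_alpha)
        correlations_fdr = dict(zip(scores, corr_rej.tolist()))
        for name, vals in (("lfp_power", lfp_pow_pat),
                           ("chan_power", chan_pow_pat)):
            for s, v in scores.items():
                controls[(name, s)] = perm_spearman(vals, v, cfg.stats, rng=rng)
    else:
        warnings.warn("fewer than 3 patients: clinical correlations skipped")

    table = pd.DataFrame({"channel": features.channels,
                          "alpha_psi_orig": mean_by_channel,
                          "alpha_psi_surr": features.psi_surr[:, :, alpha_i].mean(axis=0),
                          "flagged": [c in flagged for c in features.channels]})
    return RestAnalysisResult(anova, posthoc, fdr_rejected, flagged,
                              peak_channel, peak_mean, peak_sem, peak_test,
                              correlations, correlations_fdr, controls, table)


# ---------------------------------------------------------------------------
# suppression analysis
# ---------------------------------------------------------------------------

@dataclass
class SuppressionAnalysisResult:
    tic_rate: StatResult | None
    psi: StatResult
    lfp_power: StatResult
    chan_power: StatResult
    dropped_patients: list[str]
    n_hemispheres: int


def tic_rates(patients, condition: str) -> dict[str, float]:
    """Tics per minute in a condition's task blocks (rest recordings excluded)."""
    out = {}
    for p in patients:
        if condition not in p.sessions:
            continue
        s = p.sessions[condition]
        merged = merge_tic_sequences(s.events)
        out[p.patient_id] = len(merged.tics()) / (s.eeg.duration / 60.0)
    return out


def run_suppression_analysis(patients, cfg: AnalysisConfig) -> SuppressionAnalysisResult:
    """Tic-freely vs tic-suppression paired contrasts.

    Patients lacking a suppression session are dropped (with a log entry);
    hemispheres are the pairing unit for PSI and LFP power, patients for
    channel power and tic rate.
    """
    rng = cfg.stats.rng()
    have = [p for p in patients if "tic_suppression" in p.sessions]
    dropped = [p.patient_id for p in patients if p not in have]
    for pid in dropped:
        warnings.warn(f"patient {pid} has no suppression data; dropped")
    if len(have) < 2:
        raise ValueError("suppression analysis needs >= 2 paired patients")
    f_rest = compute_rest_features(have, cfg, conditions=("rest", "tic_freely"),
                                   rng=rng)
    f_supp = compute_rest_features(have, cfg, conditions=("tic_suppression",),
                                   rng=rng)
    alpha_i = f_rest.band_names.index("alpha")
    coi = cfg.channel_of_interest
    coi_i = f_rest.channels.index(coi)
    x_psi = f_rest.psi_orig[:, coi_i, alpha_i]
    y_psi = f_supp.psi_orig[:, coi_i, alpha_i]
    psi_t = perm_ttest_paired(x_psi, y_psi, cfg.stats, rng=rng)
    lfp_t = perm_ttest_paired(f_rest.lfp_power[:, alpha_i],
                              f_supp.lfp_power[:, alpha_i], cfg.stats, rng=rng)
    pids = list(f_rest.eeg_power)
    chan_t = perm_ttest_paired(
        np.array([f_rest.eeg_power[p][coi_i, alpha_i] for p in pids]),
        np.array([f_supp.eeg_power[p][coi_i, alpha_i] for p in pids]),
        cfg.stats, rng=rng)
    r_free = tic_rates(have, "tic_freely")
    r_supp = tic_rates(have, "tic_suppression")
    common = [p for p in r_free if p in r_supp]
    rate_t = None
    if len(common) >= 2:
        rate_t = perm_ttest_paired(np.array([r_free[p] for p in common]),
                                   np.array([r_supp[p] for p in common]),
                                   cfg.stats, rng=rng)
    return SuppressionAnalysisResult(rate_t, psi_t, lfp_t, chan_t, dropped,
                                     n_hemispheres=len(x_psi))


# ---------------------------------------------------------------------------
# tic analysis
# ---------------------------------------------------------------------------

@dataclass
class TicAnalysisResult:
    target: str
    centers: np.ndarray                  # sliding centers, s
    series: np.ndarray                   # units x centers (PSI or power)
    baselines: np.ndarray                # per unit static rest value
    rel_change: np.ndarray               # group-mean relative-change series
    window_starts: np.ndarray            # test-window left edges
    window_p: np.ndarray
    cluster: ClusterResult
    trend: TrendResult
    n_units: int
    n_trials: dict


def window_grid_starts(cfg: AnalysisConfig) -> np.ndarray:
    lo, hi = cfg.tic_range
    n = int(round((hi - cfg.test_window - lo) / cfg.test_step)) + 1
    return lo + cfg.test_step * np.arange(n)


def _window_means(values: np.ndarray, centers: np.ndarray,
                  starts: np.ndarray, width: float) -> np.ndarray:
    """Mean of sliding-series values whose centers fall in [t, t+width)."""
    out = np.empty(values.shape[:-1] + (starts.size,))
    for i, t0 in enumerate(starts):
        sel = (centers >= t0 - 1e-9) & (centers < t0 + width - 1e-9)
        out[..., i] = values[..., sel].mean(axis=-1)
    return out


def _bootstrap_baseline(values_fn, n_rest: int, n_match: int, n_boot: int,
                        rng: np.random.Generator) -> float:
    est = [values_fn(rng.integers(0, n_rest, size=n_match))
           for _ in range(n_boot)]
    return float(np.mean(est))


def run_tic_analysis(patients, cfg: AnalysisConfig,
                     targets=("psi_coi", "lfp_power", "coi_power"),
                     stream: str = "eeg",
                     min_trials: int = 5) -> dict[str, TicAnalysisResult]:
    """Event-locked sliding connectivity/power dynamics around tic onset.

    Targets: ``psi_<ch>`` (LFP-channel PSI), ``lfp_power``, ``<ch>_power``;
    ``psi_coi``/``coi_power`` resolve the configured channel of interest.
    With ``stream="source"`` the channel names refer to ROI labels of the
    supplied SOURCE recordings; patients without source signals cause the
    ROI targets to be skipped with a warning.
    """
    rng = cfg.stats.rng()
    alpha = cfg.band("alpha")
    coi = cfg.channel_of_interest if stream == "eeg" else None
    centers = sliding_centers(cfg.tic_range[0], cfg.tic_range[1], cfg.slide_step)
    starts = window_grid_starts(cfg)

    def resolve(t: str) -> tuple[str, str]:
        if t == "psi_coi":
            return ("psi", coi)
        if t == "coi_power":
            return ("power", coi)
        if t == "lfp_power":
            return ("power", "lfp")
        if t.startswith("psi_"):
            return ("psi", t[4:])
        if t.endswith("_power"):
            return ("power", t[:-6])
        raise ValueError(f"unknown target {t!r}")

    wanted_channels = sorted({resolve(t)[1] for t in targets} - {"lfp"})
    per_unit = {t: [] for t in targets}      # sliding series rows
    base = {t: [] for t in targets}
    n_trials = {}
    # the tic-locked targets are band-limited; decomposing only the alpha
    # grid keeps the wavelets short enough for the 3 s tic epochs
    freqs = np.arange(np.ceil(alpha.lo), np.floor(alpha.hi) + 1)
    for patient in patients:
        try:
            pooled_t = pooled_epochs(patient, cfg,
                                     ("rest", "tic_freely", "tic_suppression"),
                                     "tic")
            pooled_r = pooled_epochs(patient, cfg, ("rest", "tic_freely"),
                                     "rest")
        except ValueError as e:
            warnings.warn(str(e))
            continue
        ep_lfp_t, ep_tgt_t = pooled_t["lfp"], pooled_t[stream]
        ep_lfp_r, ep_tgt_r = pooled_r["lfp"], pooled_r[stream]
        if ep_tgt_t is None or ep_tgt_r is None:
            warnings.warn(f"patient {patient.patient_id}: no {stream} signals; "
                          f"targets skipped")
            continue
        if ep_lfp_t.n_trials < min_trials:
            warnings.warn(f"patient {patient.patient_id}: "
                          f"{ep_lfp_t.n_trials} tic trials < {min_trials}; skipped")
            continue
        keep = min(ep_lfp_t.n_trials, ep_tgt_t.n_trials)
        ep_lfp_t, ep_tgt_t = _truncate(ep_lfp_t, keep), _truncate(ep_tgt_t, keep)
        keep_r = min(ep_lfp_r.n_trials, ep_tgt_r.n_trials)
        ep_lfp_r, ep_tgt_r = _truncate(ep_lfp_r, keep_r), _truncate(ep_tgt_r, keep_r)
        n_trials[patient.patient_id] = keep

        tf_lfp_t = decompose(ep_lfp_t, freqs=freqs)
        tf_tgt_t = decompose(ep_tgt_t.pick(wanted_channels), freqs=freqs) \
            if wanted_channels else None
        tf_lfp_r = decompose(ep_lfp_r, freqs=freqs)
        tf_tgt_r = decompose(ep_tgt_r.pick(wanted_channels), freqs=freqs) \
            if wanted_channels else None

        for t in targets:
            kind, ch = resolve(t)
            if kind == "psi":
                for lfp_ch in ep_lfp_t.channel_labels:
                    s = psi_sliding(tf_lfp_t, tf_tgt_t, alpha,
                                    pairs=[(lfp_ch, ch)],
                                    window=cfg.slide_window,
                                    step=cfg.slide_step,
                                    t_range=cfg.tic_range)
                    per_unit[t].append(s.values[0])

                    def psi_boot(idx, _lfp=lfp_ch, _ch=ch):
                        sub_l = _subset_tf(tf_lfp_r, idx)
                        sub_t = _subset_tf(tf_tgt_r, idx)
                        v = psi_static(sub_l, sub_t, pairs=[(_lfp, _ch)])
                        return band_average(v.values[0], v.freqs, alpha)
                    base[t].append(_bootstrap_baseline(
                        psi_boot, keep_r, keep, cfg.baseline_bootstraps, rng))
            elif ch == "lfp":
                s = power_sliding(tf_lfp_t, alpha,
                                  channels=ep_lfp_t.channel_labels,
                                  window=cfg.slide_window, step=cfg.slide_step,
                                  t_range=cfg.tic_range)
                for h in range(s.values.shape[0]):
                    per_unit[t].append(s.values[h])
                raw = power_spectrum(tf_lfp_r)
                for h in range(raw.values.shape[0]):
                    base[t].append(band_average(raw.values[h], raw.freqs, alpha))
            else:
                s = power_sliding(tf_tgt_t, alpha, channels=[ch],
                                  window=cfg.slide_window, step=cfg.slide_step,
                                  t_range=cfg.tic_range)
                per_unit[t].append(s.values[0])
                raw = power_spectrum(tf_tgt_r)
                base[t].append(band_average(
                    raw.values[raw.channel_labels.index(ch)], raw.freqs, alpha))

    out = {}
    for t in targets:
        series = np.asarray(per_unit[t])
        if series.shape[0] < 2:
            warnings.warn(f"target {t}: fewer than 2 units; skipped")
            continue
        baselines = np.asarray(base[t])
        win_vals = _window_means(series, centers, starts, cfg.test_window)
        pvals = np.empty(starts.size)
        for i in range(starts.size):
            pvals[i] = perm_ttest_paired(win_vals[:, i], baselines,
                                         cfg.stats, rng=rng).p_mc
        cluster = cluster_mcs(pvals, cfg.stats, rng=rng)
        rel = relative_change(series, baselines).mean(axis=0)
        pre = centers <= 0 + 1e-9
        trend = linreg_trend(centers[pre], series.mean(axis=0)[pre],
                             cfg.stats, rng=rng)
        out[t] = TicAnalysisResult(t, centers, series, baselines, rel,
                                   starts, pvals, cluster, trend,
                                   series.shape[0], n_trials)
    return out


def _subset_tf(tf, idx):
    from .spectral import TFDecomposition

    return TFDecomposition(tf.coeffs[idx], tf.freqs, tf.rate, tf.times,
                           list(tf.channel_labels), tf.n_cycles, tf.valid)
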