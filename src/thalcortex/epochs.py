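"""Tic selection rules and epoch extraction.

Tic annotations are cleaned in two steps before epoching: tics separated by
less than 2 s are merged into a single tic sequence spanning from the first
onset to the last offset, and only tics preceded by a tic-free interval of
at least 2 s (inclusive) are retained, so every analysed tic has a clean
pre-onset baseline.

Three epoch types are produced: tic epochs cut around tic onsets (default
window -2.1 to 0.9 s, padding the -1.8 to 0.6 s analysis range by 0.3 s for
sliding-window edge support), 4-s rest epochs tiled greedily into tic- and
movement-free stretches of the tic-freely data, and suppression epochs (rest
epochs extracted from the tic-suppression condition).  EEG is expected to be
resampled to the LFP rate before epoching so both streams share a time base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .io_formats import EventTable, Recording

MERGE_GAP_S = 2.0        # tics closer than this form one sequence
ISOLATION_S = 2.0        # required tic-free history before an analysed tic
REST_MARGIN_S = 1.0      # guard margin around tic/movement events


@dataclass
class EpochSet:
    """Trials x channels x samples cut around a common anchor."""

    data: np.ndarray
    rate: float
    window: tuple[float, float]   # seconds relative to anchor
    anchor: str                   # "tic_onset" | "segment_start"
    channel_labels: list[str]
    condition: str = ""
    trial_meta: pd.DataFrame = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[0] < 1:
            raise ValueError("epoch set must contain at least one trial")
        n_expected = int(round((self.window[1] - self.window[0]) * self.rate))
        if abs(self.data.shape[2] - n_expected) > 1:
            raise ValueError("window length inconsistent with sample count")
        if self.trial_meta is None:
            self.trial_meta = pd.DataFrame(index=range(self.data.shape[0]))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def pick(self, labels: list[str]) -> "EpochSet":
        idx = [self.channel_labels.index(l) for l in labels]
        return EpochSet(self.data[:, idx], self.rate, self.window, self.anchor,
                        list(labels), self.condition,
                        self.trial_meta.copy(), dict(self.meta))

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["rate"] = self.rate
            f.attrs["window"] = self.window
            f.attrs["anchor"] = self.anchor
            f.attrs["condition"] = self.condition
            f.attrs["channel_labels"] = [str(c) for c in self.channel_labels]

    @classmethod
    def load(cls, path) -> "EpochSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["data"][()], float(f.attrs["rate"]),
                       tuple(f.attrs["window"]), str(f.attrs["anchor"]),
                       [str(c) for c in f.attrs["channel_labels"]],
                       str(f.attrs["condition"]))


# ---------------------------------------------------------------------------
# tic selection rules
# ---------------------------------------------------------------------------

def merge_tic_sequences(events: EventTable, gap: float = MERGE_GAP_S) -> EventTable:
    """Merge runs of tics separated by less than ``gap`` seconds.

    A merged sequence spans from the first tic's onset to the last tic's
    offset and inherits the first tic's condition label; overlapping tics
    are merged with a warning.  Non-tic events pass through unchanged.
    """
    tic = events.df[events.df["kind"] == "tic"]
    rest = events.df[events.df["kind"] != "tic"]
    merged = []
    for row in tic.itertuples():
        if merged and row.onset - merged[-1]["offset"] < gap:
            if row.onset < merged[-1]["offset"]:
                warnings.warn("overlapping tic annotations merged")
            merged[-1]["offset"] = max(merged[-1]["offset"], row.offset)
            merged[-1]["n_merged"] += 1
        else:
            merged.append({"onset": row.onset, "offset": row.offset,
                           "kind": "tic", "tic_type": row.tic_type,
                           "condition": row.condition, "n_merged": 1})
    for m in merged:
        if m.pop("n_merged") > 1:
            m["tic_type"] = (m["tic_type"] + " sequence").strip()
    out = pd.concat([pd.DataFrame(merged, columns=rest.columns if not merged else None),
                     rest], ignore_index=True)
    return EventTable(out)


def select_isolated_tics(events: EventTable,
                         isolation: float = ISOLATION_S) -> EventTable:
    """Keep tics preceded by a tic-free interval of at least ``isolation`` s.

    The bound is inclusive: a previous tic ending exactly ``isolation``
    seconds before the onset does not disqualify the tic.  Apply after
    :func:`merge_tic_sequences`.
    """
    df = events.df
    tic = df[df["kind"] == "tic"].reset_index(drop=True)
    keep = []
    offsets = tic["offset"].to_numpy()
    onsets = tic["onset"].to_numpy()
    for i in range(len(tic)):
        prior = offsets[(onsets < onsets[i]) & (offsets > onsets[i] - isolation)]
        keep.append(prior.size == 0)
    out = pd.concat([tic[np.array(keep, dtype=bool)] if len(tic) else tic,
                     df[df["kind"] != "tic"]], ignore_index=True)
    return EventTable(out)


# ---------------------------------------------------------------------------
# epoch extraction
# ---------------------------------------------------------------------------

def _cut(rec: Recording, anchors: np.ndarray, window: tuple[float, float],
         time_map=None):
    """Slice fixed-length windows around anchor times (reference clock).

    ``time_map`` converts reference-clock seconds into this recording's
    clock (e.g. ``sync.b_to_a`` for the LFP stream).  Out-of-bounds trials
    are dropped and counted.
    """
    t = np.asarray(anchors, dtype=float)
    if time_map is not None:
        t = np.asarray(time_map(t), dtype=float)
    t = t - rec.start_offset
    n = int(round((window[1] - window[0]) * rec.rate))
    starts = np.round((t + window[0]) * rec.rate).astype(int)
    ok = (starts >= 0) & (starts + n <= rec.n_samples)
    trials = np.stack([rec.data[:, s:s + n] for s in starts[ok]]) \
        if ok.any() else np.empty((0, rec.n_channels, n))
    return trials, ok


def extract_tic_epochs(rec: Recording, events: EventTable,
                       window: tuple[float, float] = (-2.1, 0.9),
                       time_map=None, condition: str | None = None) -> EpochSet:
    """One trial per (merged, isolated) tic, anchored at tic onset."""
    tics = events.tics(condition)
    if len(tics) == 0:
        raise ValueError("no tic events to epoch")
    onsets = tics.df["onset"].to_numpy()
    trials, ok = _cut(rec, onsets, window, time_map)
    if trials.shape[0] == 0:
        raise ValueError("no tic epoch fits within the recording bounds")
    meta = tics.df.loc[ok, ["onset", "condition", "tic_type"]].reset_index(drop=True)
    return EpochSet(trials, rec.rate, window, "tic_onset",
                    list(rec.channel_labels),
                    condition=condition or "pooled", trial_meta=meta,
                    meta={"n_dropped": int((~ok).sum())})


def rest_segment_starts(events: EventTable, duration: float,
                        length: float = 4.0,
                        margin: float = REST_MARGIN_S) -> np.ndarray:
    """Greedy left-to-right tiling of epoch start times outside events.

    Tic and movement intervals, padded by ``margin`` on both sides, are
    excluded; epochs never overlap.
    """
    df = events.df
    bad = df[df["kind"].isin(["tic", "movement", "artifact_sync"])]
    intervals = sorted((max(r.onset - margin, 0.0), r.offset + margin)
                       for r in bad.itertuples())
    free, cursor = [], 0.0
    for lo, hi in intervals:
        if lo > cursor:
            free.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < duration:
        free.append((cursor, duration))
    starts = []
    for lo, hi in free:
        k = int(np.floor((hi - lo) / length + 1e-9))
        starts.extend(lo + i * length for i in range(k))
    return np.asarray(starts)


def extract_rest_epochs(rec: Recording, events: EventTable,
                        length: float = 4.0, margin: float = REST_MARGIN_S,
                        time_map=None, condition: str = "tic_freely",
                        duration: float | None = None) -> EpochSet:
    """Non-overlapping rest epochs fully outside tic/movement events.

    ``duration`` bounds the reference-clock span searched for segments
    (defaults to the recording's own duration).
    """
    n = length * rec.rate
    flagged = []
    if abs(n - round(n)) > 1e-9:
        flagged.append("epoch length rounded down to a whole sample count")
        warnings.warn(flagged[-1])
    length_eff = np.floor(n) / rec.rate
    duration = duration if duration is not None else rec.duration
    starts = rest_segment_starts(events, duration, length_eff, margin)
    if starts.size == 0:
        raise ValueError("no rest segment available outside events")
    trials, ok = _cut(rec, starts, (0.0, length_eff), time_map)
    if trials.shape[0] == 0:
        raise ValueError("no rest segment fits within the recording bounds")
    meta = pd.DataFrame({"onset": starts[ok]})
    return EpochSet(trials, rec.rate, (0.0, length_eff), "segment_start",
                    list(rec.channel_labels), condition=condition,
                    trial_meta=meta,
                    meta={"n_dropped": int((~ok).sum()), "flags": flagged})


def extract_epochs_at(rec: Recording, anchors, window: tuple[float, float],
                      time_map=None, anchor: str = "segment_start",
                      condition: str = "") -> EpochSet:
    """Cut epochs at explicit reference-clock anchor times.

    Used to cut the LFP stream at the very same anchors as the EEG stream
    (mapped through the fitted clock model) so the two epoch sets stay
    sample-aligned.
    """
    trials, ok = _cut(rec, anchors, window, time_map)
    if trials.shape[0] == 0:
        raise ValueError("no epoch fits within the recording bounds")
    meta = pd.DataFrame({"onset": np.asarray(anchors, dtype=float)[ok]})
    return EpochSet(trials, rec.rate, window, anchor,
                    list(rec.channel_labels), condition=condition,
                    trial_meta=meta, meta={"n_dropped": int((~ok).sum())})


def pool_conditions(*epochsets: EpochSet) -> EpochSet:
    """Concatenate trials across conditions, keeping provenance."""
    sets = [e for e in epochsets if e is not None]
    if not sets:
        raise ValueError("nothing to pool")
    first = sets[0]
    for e in sets[1:]:
        if e.rate != first.rate or e.window != first.window \
                or e.channel_labels != first.channel_labels:
            raise ValueError("cannot pool epoch sets with mismatched geometry")
    data = np.concatenate([e.data for e in sets], axis=0)
    meta = pd.concat([e.trial_meta.assign(condition=e.condition)
                      for e in sets], ignore_index=True)
    return EpochSet(data, first.rate, first.window, first.anchor,
                    list(first.channel_labels), condition="pooled",
                    trial_meta=meta)


def resample_recording(rec: Recording, target_rate: float) -> Recording:
    """Polyphase resampling to a common analysis rate (e.g. EEG 5000->250 Hz)."""
    if target_rate == rec.rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    meta = dict(rec.meta)
    meta["resampled_from"] = rec.rate
    return Recording(data, target_rate, list(rec.channel_labels),
                     rec.modality, rec.start_offset, meta)
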