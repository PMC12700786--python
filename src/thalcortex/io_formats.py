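"""Readers and writers for the recording formats of combined DBS-LFP + EEG sessions.

Two acquisition streams are handled: bipolar thalamic local field potentials
streamed by a sensing-enabled pulse generator (Percept-style JSON, 250 Hz,
one channel per hemisphere) and high-density scalp EEG stored as BrainVision
``.vhdr``/``.vmrk``/``.eeg`` triplets (63 channels, 5000 Hz).  The two streams
run on independent clocks; stimulation-artifact markers present in both are
used to fit a linear clock map (:func:`synchronize_streams`).

All event times are referenced to the EEG clock; the LFP clock is mapped
through the fitted :class:`SyncModel`.  Clinical severity scores are loaded
from plain CSV tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class Modality(str, Enum):
    LFP = "LFP"
    EEG = "EEG"
    SOURCE = "SOURCE"


class FormatError(ValueError):
    """Raised when an input file does not follow the expected schema."""


EVENT_KINDS = ("tic", "artifact_sync", "block_boundary", "movement")
CONDITIONS = ("rest", "tic_freely", "tic_suppression")
EVENT_COLUMNS = ("onset", "offset", "kind", "tic_type", "condition")

HEMISPHERES = ("left", "right")


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Labelled multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names. For LFP the labels identify the hemisphere
        (``"lfp_left"`` / ``"lfp_right"``).
    modality : Modality
        LFP, EEG or SOURCE (externally reconstructed ROI time series).
    start_offset : float
        Start time of sample 0 in this stream's own clock, seconds.
    meta : dict
        Free-form provenance (device, sensing contacts, detected gaps, ...).
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    modality: Modality
    start_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN; gaps must be flagged in meta")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length mismatch")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        self.modality = Modality(self.modality)
        if self.modality is Modality.LFP and not 1 <= self.data.shape[0] <= 2:
            raise ValueError("LFP recordings carry 1-2 hemisphere channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def pick(self, labels: list[str]) -> "Recording":
        idx = [self.channel_labels.index(l) for l in labels]
        return Recording(self.data[idx], self.rate, list(labels), self.modality,
                         self.start_offset, dict(self.meta))


class EventTable:
    """Annotations (tics, sync artifacts, block boundaries, movement).

    Wraps a DataFrame with columns ``onset, offset, kind, tic_type,
    condition``; rows are kept sorted by onset.  Times are seconds on the
    session's reference (EEG) clock unless stated otherwise.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=list(EVENT_COLUMNS))
        df = df.copy()
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col in ("tic_type", "condition", "kind") else np.nan
        df = df[list(EVENT_COLUMNS)]
        df["onset"] = df["onset"].astype(float)
        df["offset"] = df["offset"].astype(float)
        df["tic_type"] = df["tic_type"].fillna("").astype(str)
        df["condition"] = df["condition"].fillna("").astype(str)
        if len(df):
            if (df["offset"] < df["onset"]).any():
                raise ValueError("event offset before onset")
            bad = ~df["kind"].isin(EVENT_KINDS)
            if bad.any():
                raise ValueError(f"unknown event kind(s): {sorted(df.loc[bad, 'kind'].unique())}")
            tic = df["kind"] == "tic"
            if (df.loc[tic, "condition"] == "").any():
                raise ValueError("tic events must carry a condition label")
            df = df.sort_values("onset", kind="stable").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)

    @classmethod
    def from_records(cls, rows: list[dict]) -> "EventTable":
        return cls(pd.DataFrame(rows))

    def of_kind(self, kind: str) -> "EventTable":
        return EventTable(self.df[self.df["kind"] == kind])

    def tics(self, condition: str | None = None) -> "EventTable":
        sel = self.df["kind"] == "tic"
        if condition is not None:
            sel &= self.df["condition"] == condition
        return EventTable(self.df[sel])

    def concat(self, other: "EventTable") -> "EventTable":
        return EventTable(pd.concat([self.df, other.df], ignore_index=True))

    def shifted(self, dt: float) -> "EventTable":
        df = self.df.copy()
        df["onset"] += dt
        df["offset"] += dt
        return EventTable(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path, keep_default_na=False,
                               dtype={"tic_type": str, "condition": str}))


@dataclass
class ClinicalRecord:
    """One patient's severity scores and implant metadata."""

    patient_id: str
    ygtss_tts: float
    ygtss_global: float
    puts: float
    months_since_op: float
    dbs_target: str = "CM_Voi"
    ipg_side: str = "left"

    def __post_init__(self):
        for name in ("ygtss_tts", "ygtss_global", "puts", "months_since_op"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ygtss_tts > self.ygtss_global:
            raise ValueError("YGTSS total tic score cannot exceed the global score")
        if self.dbs_target not in ("CM_Voi", "VA_VL"):
            raise ValueError(f"unknown DBS target {self.dbs_target!r}")
        if self.ipg_side not in ("left", "right"):
            raise ValueError(f"unknown IPG side {self.ipg_side!r}")


@dataclass
class SyncModel:
    """Linear clock map between two streams: ``t_b = offset + (1 + drift) * t_a``.

    Fitted from stimulation-artifact markers present in both streams.
    ``drift`` is dimensionless (seconds of clock b per second of clock a,
    minus one).  ``offset_only`` flags a degenerate fit from a single marker
    pair, where drift could not be estimated.
    """

    offset: float
    drift: float = 0.0
    residual_rms: float = 0.0
    n_markers: int = 0
    offset_only: bool = False

    def a_to_b(self, t):
        return self.offset + (1.0 + self.drift) * np.asarray(t, dtype=float)

    def b_to_a(self, t):
        return (np.asarray(t, dtype=float) - self.offset) / (1.0 + self.drift)


# ---------------------------------------------------------------------------
# Percept-style streaming JSON
# ---------------------------------------------------------------------------
# Only the time-domain streaming subset of the device schema is supported:
# per-channel sample arrays, the declared sampling rate, hemisphere metadata,
# and packet tick times from which sample gaps are reconstructed.  Any other
# top-level keys are carried through as opaque metadata.

_PACKET = 250  # samples per packet written by write_percept_json


def write_percept_json(rec: Recording, path) -> None:
    """Write an LFP recording as a Percept-style BrainSense streaming JSON.

    Gaps listed in ``rec.meta["gaps"]`` (``{"sample": i, "n_samples": m}``)
    are encoded as jumps in the packet tick times, as a streaming dropout
    would appear in a real export.  Round-trips bit-exactly through
    :func:`read_percept_json`.
    """
    if Modality(rec.modality) is not Modality.LFP:
        raise ValueError("write_percept_json only writes LFP recordings")
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    gaps = sorted(rec.meta.get("gaps", []), key=lambda g: g["sample"])
    hemis = rec.meta.get("hemisphere", {})
    channels = []
    for ci, label in enumerate(rec.channel_labels):
        samples = rec.data[ci]
        ticks, sizes = [], []
        t_ms = rec.start_offset * 1000.0
        for start in range(0, rec.n_samples, _PACKET):
            size = min(_PACKET, rec.n_samples - start)
            for g in gaps:
                if start - 1 < g["sample"] <= start:
                    t_ms += g["n_samples"] / rec.rate * 1000.0
            ticks.append(t_ms)
            sizes.append(size)
            t_ms += size / rec.rate * 1000.0
        channels.append({
            "Channel": label,
            "Hemisphere": hemis.get(label, HEMISPHERES[ci % 2]),
            "SampleRateInHz": rec.rate,
            "TimeDomainData": samples.tolist(),
            "TicksInMs": ticks,
            "GlobalPacketSizes": sizes,
        })
    doc = {
        "DeviceInformation": rec.meta.get("device", {"Neurostimulator": "synthetic"}),
        "BrainSenseTimeDomain": channels,
    }
    Path(path).write_text(json.dumps(doc))


def read_percept_json(path) -> Recording:
    """Read the time-domain streaming section of a Percept-style JSON export.

    Sample gaps are detected from discontinuities in the packet tick times
    and recorded in ``meta["gaps"]``; the data array itself is never padded.
    A mismatch between declared packet sizes and the sample count is recorded
    as a warning in ``meta``, not raised.
    """
    doc = json.loads(Path(path).read_text())
    tds = doc.get("BrainSenseTimeDomain")
    if not tds:
        raise FormatError("no BrainSenseTimeDomain section in JSON export")
    data, labels, hemis, gaps = [], [], {}, []
    rate = None
    meta_warnings = []
    start_offset = None
    for ch in tds:
        if "SampleRateInHz" not in ch:
            raise FormatError("channel without SampleRateInHz field")
        if "TimeDomainData" not in ch:
            raise FormatError("channel without TimeDomainData section")
        r = float(ch["SampleRateInHz"])
        if rate is None:
            rate = r
        elif r != rate:
            raise FormatError("channels declare inconsistent sampling rates")
        label = ch.get("Channel", f"ch{len(labels)}")
        labels.append(label)
        hemis[label] = ch.get("Hemisphere", "")
        samples = np.asarray(ch["TimeDomainData"], dtype=np.float64)
        data.append(samples)
        ticks = ch.get("TicksInMs")
        sizes = ch.get("GlobalPacketSizes")
        if ticks is not None and sizes is not None:
            if start_offset is None:
                start_offset = ticks[0] / 1000.0
            if int(sum(sizes)) != samples.size:
                meta_warnings.append(
                    f"channel {label}: declared {int(sum(sizes))} samples, "
                    f"found {samples.size}")
            sample_pos = 0
            for k in range(len(ticks) - 1):
                sample_pos += sizes[k]
                expected = ticks[k] + sizes[k] / rate * 1000.0
                jump_ms = ticks[k + 1] - expected
                n_missing = int(round(jump_ms / 1000.0 * rate))
                if n_missing > 0 and label == labels[0]:
                    gaps.append({"sample": sample_pos, "n_samples": n_missing})
    lengths = {d.size for d in data}
    if len(lengths) != 1:
        raise FormatError("channels have unequal sample counts")
    meta = {"hemisphere": hemis, "gaps": gaps,
            "device": doc.get("DeviceInformation", {})}
    if meta_warnings:
        meta["warnings"] = meta_warnings
        for w in meta_warnings:
            warnings.warn(w)
    return Recording(np.vstack(data), rate, labels, Modality.LFP,
                     start_offset=start_offset or 0.0, meta=meta)


# ---------------------------------------------------------------------------
# BrainVision triplets
# ---------------------------------------------------------------------------

_BV_FORMATS = {"IEEE_FLOAT_32": np.float32, "INT_16": np.int16}


def write_brainvision(rec: Recording, events: EventTable, path_vhdr,
                      orientation: str = "MULTIPLEXED",
                      binary_format: str = "IEEE_FLOAT_32",
                      resolution: float = 0.1) -> None:
    """Write a BrainVision ``.vhdr``/``.vmrk``/``.eeg`` triplet.

    Both binary orientations (MULTIPLEXED / VECTORIZED) and both sample
    formats (IEEE float32 in µV at resolution 1; int16 scaled by
    ``resolution`` µV/bit) are supported.  Events are stored as stimulus
    markers whose description encodes ``kind;condition;tic_type``.
    """
    orientation = orientation.upper()
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if binary_format not in _BV_FORMATS:
        raise ValueError(f"unknown binary format {binary_format!r}")
    path_vhdr = Path(path_vhdr)
    stem = path_vhdr.with_suffix("")
    eeg_name, vmrk_name = stem.name + ".eeg", stem.name + ".vmrk"

    res = 1.0 if binary_format == "IEEE_FLOAT_32" else resolution
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by thalcortex",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        f"DataOrientation={orientation}",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.rate:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,{res:g},µV")
    path_vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    if binary_format == "IEEE_FLOAT_32":
        out = rec.data.astype(np.float32)
    else:
        out = np.round(rec.data / res).astype(np.int16)
    if orientation == "MULTIPLEXED":
        out = out.T  # sample-major
    out.tofile(stem.with_suffix(".eeg"))

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, row in enumerate(events.df.itertuples(), start=2):
        desc = ";".join(str(x).replace(",", " ") for x in
                        (row.kind, row.condition, row.tic_type))
        pos = int(round((row.onset - rec.start_offset) * rec.rate)) + 1
        dur = int(round((row.offset - row.onset) * rec.rate))
        mlines.append(f"Mk{k}=Stimulus,{desc},{pos},{dur},0")
    stem.with_suffix(".vmrk").write_text("\n".join(mlines) + "\n", encoding="utf-8")


def read_brainvision(path_vhdr) -> tuple[Recording, EventTable]:
    """Read a BrainVision triplet into a Recording plus its marker events.

    Reading is delegated to :func:`mne.io.read_raw_brainvision`; data are
    returned in µV.  Stimulus markers written by :func:`write_brainvision`
    are decoded back into an :class:`EventTable`; foreign marker
    descriptions become ``movement`` events so no annotation is dropped
    silently.
    """
    import mne

    path_vhdr = Path(path_vhdr)
    for suffix in (".vhdr", ".vmrk", ".eeg"):
        if not path_vhdr.with_suffix(suffix).exists():
            raise FormatError(f"missing BrainVision sidecar {suffix}")
    raw = mne.io.read_raw_brainvision(path_vhdr, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    rec = Recording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                    Modality.EEG, meta={"source_file": path_vhdr.name})
    rows = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("New Segment"):
            continue
        payload = desc.split("/", 1)[-1]
        parts = payload.split(";")
        kind = parts[0] if parts[0] in EVENT_KINDS else "movement"
        rows.append({
            "onset": float(ann["onset"]),
            "offset": float(ann["onset"]) + float(ann["duration"]),
            "kind": kind,
            "condition": parts[1] if len(parts) > 1 else "",
            "tic_type": parts[2] if len(parts) > 2 else "",
        })
    return rec, EventTable.from_records(rows) if rows else EventTable()


# ---------------------------------------------------------------------------
# stream synchronisation
# ---------------------------------------------------------------------------

def synchronize_streams(events_a: EventTable, events_b: EventTable) -> SyncModel:
    """Fit the clock map ``t_b = offset + (1 + drift) * t_a`` from sync markers.

    Stimulation-artifact markers are matched by rank order (the artifacts
    are induced at the start and end of each streaming, so ordering
    identifies them).  With a single matched pair only the offset can be
    estimated; the model is then flagged ``offset_only``.
    """
    ta = events_a.of_kind("artifact_sync").df["onset"].to_numpy()
    tb = events_b.of_kind("artifact_sync").df["onset"].to_numpy()
    n = min(ta.size, tb.size)
    if n == 0:
        raise ValueError("no matched sync markers in one of the streams")
    ta, tb = ta[:n], tb[:n]
    if n == 1:
        return SyncModel(offset=float(tb[0] - ta[0]), drift=0.0,
                         residual_rms=0.0, n_markers=1, offset_only=True)
    X = np.column_stack([np.ones(n), ta])
    coef, *_ = np.linalg.lstsq(X, tb, rcond=None)
    resid = tb - X @ coef
    return SyncModel(offset=float(coef[0]), drift=float(coef[1] - 1.0),
                     residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                     n_markers=int(n))


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_CLINICAL_REQUIRED = ("patient_id", "ygtss_tts", "ygtss_global", "puts",
                      "months_since_op")


def load_clinical_table(path) -> list[ClinicalRecord]:
    """Load a clinical-score CSV (one row per patient) into records.

    Required columns: ``patient_id, ygtss_tts, ygtss_global, puts,
    months_since_op``; optional: ``dbs_target, ipg_side``.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise FormatError("clinical table is empty") from e
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing column(s): {missing}")
    if len(df) == 0:
        raise FormatError("clinical table has no rows")
    records = []
    for row in df.itertuples():
        kwargs = {}
        if "dbs_target" in df.columns:
            kwargs["dbs_target"] = str(row.dbs_target)
        if "ipg_side" in df.columns:
            kwargs["ipg_side"] = str(row.ipg_side)
        records.append(ClinicalRecord(
            patient_id=str(row.patient_id),
            ygtss_tts=float(row.ygtss_tts),
            ygtss_global=float(row.ygtss_global),
            puts=float(row.puts),
            months_since_op=float(row.months_since_op),
            **kwargs))
    return records


def summarize_cohort(records: list[ClinicalRecord],
                     fields=("ygtss_tts", "ygtss_global", "puts",
                             "months_since_op")) -> pd.DataFrame:
    """Per-field mean, sample SD (n-1 denominator), min and max."""
    if len(records) < 2:
        raise ValueError("cohort summary needs at least 2 records")
    rows = {}
    for f in fields:
        v = np.array([getattr(r, f) for r in records], dtype=float)
        rows[f] = {"mean": v.mean(), "sd": v.std(ddof=1),
                   "min": v.min(), "max": v.max(), "n": v.size}
    return pd.DataFrame(rows).T


def write_clinical_table(records: list[ClinicalRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)
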