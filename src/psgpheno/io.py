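"""Recording, hypnogram and event-list containers and their on-disk formats.

The on-disk contracts are deliberately plain: EDF (not EDF+) for signals,
with annotations carried in sidecar CSVs — a hypnogram CSV with header
``epoch_index,start_s,label`` and an events CSV with header
``onset_s,duration_s,type,channel``.  All sample intervals are half-open
and 0-based.
"""

from __future__ import annotations

import datetime as _dt
import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed set of hypnogram state labels.
STATES = ("WAKE", "NREM", "REM", "ARTIFACT")

#: Default EDF physical range, in µV (±2 mV).
EDF_PHYS_MAX_UV = 2000.0

EDF_DIG_MIN = -32768
EDF_DIG_MAX = 32767


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


class AlignmentError(ValueError):
    """Raised when a hypnogram cannot be aligned to a recording."""


@dataclass
class Recording:
    """A multichannel physiological recording in physical units (µV).

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Per-channel samples, all at the same sampling rate.
    sampling_rate : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique channel labels (e.g. ``"EEG FC-L"``, ``"EMG"``).
    start_time : datetime.datetime
        Clock time of the first sample.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_labels: Sequence[str]
    start_time: _dt.datetime

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if len(self.channel_labels) == 0:
            raise FormatError("a recording requires at least one channel")
        if self.signals.shape[0] != len(self.channel_labels):
            raise FormatError(
                f"{self.signals.shape[0]} signal rows for "
                f"{len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def eeg_indices(self) -> list[int]:
        """Indices of EEG channels (labels starting with ``"EEG"``).

        Falls back to all channels when no label carries the prefix.
        """
        idx = [i for i, lb in enumerate(self.channel_labels) if lb.upper().startswith("EEG")]
        return idx if idx else list(range(self.n_channels))


@dataclass
class Hypnogram:
    """A sequence of fixed-length epoch state labels."""

    labels: Sequence[str]
    epoch_s: float = 4.0
    start_time: _dt.datetime | None = None

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise FormatError("epoch_s must be positive")
        bad = sorted({lb for lb in self.labels if lb not in STATES})
        if bad:
            raise FormatError(f"unknown state labels: {bad}; allowed: {STATES}")
        self.labels = list(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_s

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


@dataclass
class EventList:
    """Sorted list of (onset_s, duration_s, type, channel) event records."""

    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["onset_s", "duration_s", "type", "channel"]
        )
    )

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events, columns=["onset_s", "duration_s", "type", "channel"])
        ev = ev.sort_values("onset_s", kind="stable").reset_index(drop=True)
        if len(ev) and (ev["duration_s"] < 0).any():
            raise FormatError("event durations must be >= 0")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording(recording: Recording, path: str | Path,
                    phys_max: float = EDF_PHYS_MAX_UV) -> None:
    """Write a Recording to a 16-bit EDF file.

    Samples are quantized into the symmetric physical range ``±phys_max``
    (µV); values outside the range are clipped.  The recording must contain
    a whole number of 1 s data records.
    """
    path = Path(path)
    if recording.n_channels == 0:
        raise FormatError("cannot write an EDF with no channels")
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records, rem = divmod(recording.n_samples, fs)
    if rem:
        raise FormatError(
            "EDF writer requires a whole number of 1 s records "
            f"(got {recording.n_samples} samples at {fs} Hz)"
        )
    ns = recording.n_channels
    st = recording.start_time
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field(st.strftime("%d.%m.%y"), 8),
        _edf_field(st.strftime("%H.%M.%S"), 8),
        _edf_field(str(256 * (ns + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(ns), 4),
    ])
    per = b"".join([
        b"".join(_edf_field(lb, 16) for lb in recording.channel_labels),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{-phys_max:g}", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{phys_max:g}", 8) for _ in range(ns)),
        b"".join(_edf_field(str(EDF_DIG_MIN), 8) for _ in range(ns)),
        b"".join(_edf_field(str(EDF_DIG_MAX), 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(str(fs), 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])
    scale = (EDF_DIG_MAX - EDF_DIG_MIN) / (2 * phys_max)
    clipped = np.clip(recording.signals, -phys_max, phys_max)
    digital = np.rint((clipped + phys_max) * scale + EDF_DIG_MIN).astype("<i2")
    # records interleave channels: (record, channel, sample-in-record)
    interleaved = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per)
        fh.write(interleaved.tobytes())


def read_recording(path: str | Path) -> Recording:
    """Read a 16-bit EDF file into a Recording (physical units)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header")
    try:
        date_s = raw[168:176].decode("ascii").strip()
        time_s = raw[176:184].decode("ascii").strip()
        n_records = int(raw[236:244])
        record_dur = float(raw[244:252])
        ns = int(raw[252:256])
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: malformed EDF header ({exc})") from exc
    if ns <= 0:
        raise FormatError(f"{path}: EDF declares {ns} signals")
    hdr_len = 256 + ns * 256
    if len(raw) < hdr_len:
        raise FormatError(f"{path}: truncated EDF signal headers")

    def fields(offset: int, width: int) -> list[str]:
        base = 256 + offset * ns
        return [
            raw[base + i * width: base + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]

    labels = fields(0, 16)
    phys_min = np.array([float(v) for v in fields(96 + 8, 8)])   # after transducer+dim
    phys_max = np.array([float(v) for v in fields(96 + 8 + 8, 8)])
    dig_min = np.array([float(v) for v in fields(96 + 8 + 16, 8)])
    dig_max = np.array([float(v) for v in fields(96 + 8 + 24, 8)])
    nsamp = [int(v) for v in fields(96 + 8 + 32 + 80, 8)]
    if len(set(nsamp)) != 1:
        raise FormatError(f"{path}: per-channel record sizes differ: {sorted(set(nsamp))}")
    spr = nsamp[0]
    fs = spr / record_dur
    expected = hdr_len + n_records * ns * spr * 2
    if len(raw) < expected:
        raise FormatError(
            f"{path}: EDF data truncated ({len(raw)} bytes, expected {expected})"
        )
    data = np.frombuffer(raw[hdr_len:expected], dtype="<i2")
    data = data.reshape(n_records, ns, spr).transpose(1, 0, 2).reshape(ns, -1)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    signals = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    try:
        day, month, year = (int(v) for v in date_s.split("."))
        hh, mm, ss = (int(v) for v in time_s.split("."))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF start date/time") from exc
    year += 1900 if year >= 85 else 2000
    start = _dt.datetime(year, month, day, hh, mm, ss)
    return Recording(signals=signals, sampling_rate=fs,
                     channel_labels=labels, start_time=start)


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram to CSV (``epoch_index,start_s,label``)."""
    df = pd.DataFrame({
        "epoch_index": np.arange(len(hypnogram)),
        "start_s": np.arange(len(hypnogram)) * hypnogram.epoch_s,
        "label": list(hypnogram.labels),
    })
    df.to_csv(path, index=False)


def read_hypnogram(path: str | Path, epoch_s: float = 4.0) -> Hypnogram:
    """Read a hypnogram CSV; unknown state labels are rejected.

    An empty file (or header-only file) yields an empty hypnogram with a
    logged warning, so that pipelines can distinguish "nothing scored" from
    a malformed file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty hypnogram file", path)
        warnings.warn(f"{path}: empty hypnogram file", stacklevel=2)
        return Hypnogram(labels=[], epoch_s=epoch_s)
    if df.empty:
        logger.warning("%s: hypnogram file has no rows", path)
        warnings.warn(f"{path}: hypnogram file has no rows", stacklevel=2)
        return Hypnogram(labels=[], epoch_s=epoch_s)
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    bad = ~df["label"].isin(STATES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: unknown state label {df['label'].iloc[row]!r} at row {row}"
        )
    if "start_s" in df.columns and len(df) > 1:
        steps = np.diff(df["start_s"].to_numpy(dtype=float))
        epoch_s = float(steps[0])
        if not np.allclose(steps, epoch_s):
            raise FormatError(f"{path}: non-uniform epoch starts")
    return Hypnogram(labels=df["label"].tolist(), epoch_s=epoch_s)


# ---------------------------------------------------------------------------
# Events CSV
# ---------------------------------------------------------------------------

def write_events(events: EventList, path: str | Path) -> None:
    events.events.to_csv(path, index=False)


def read_events(path: str | Path) -> EventList:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return EventList()
    missing = {"onset_s", "duration_s", "type", "channel"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing event columns {sorted(missing)}")
    return EventList(events=df)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_hypnogram(recording: Recording, hypnogram: Hypnogram) -> np.ndarray:
    """Map hypnogram epochs onto half-open sample intervals.

    Returns an integer array of shape ``(n_epochs, 2)`` where epoch *k*
    covers samples ``[k*L*fs, (k+1)*L*fs)``.
    """
    spe = hypnogram.epoch_s * recording.sampling_rate
    if abs(spe - round(spe)) > 1e-9:
        raise AlignmentError(
            f"epoch length {hypnogram.epoch_s}s is not a whole number of samples "
            f"at {recording.sampling_rate} Hz"
        )
    spe = int(round(spe))
    n_epochs = len(hypnogram)
    if n_epochs * spe > recording.n_samples:
        raise AlignmentError(
            f"hypnogram spans {n_epochs * spe} samples but recording has "
            f"{recording.n_samples}"
        )
    starts = np.arange(n_epochs, dtype=np.int64) * spe
    return np.stack([starts, starts + spe], axis=1)
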