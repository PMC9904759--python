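"""Artifact exclusion, detrending, 60 Hz notch filtering, analysis-hour schedule.

The fixed pipeline order is: artifact exclusion → mean detrend → zero-phase
Butterworth notch.  Excluded windows are dropped from downstream Welch
segment formation (never zero-filled).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording

#: Saturation guard: samples at/above this |amplitude| (µV) flag the window.
SATURATION_UV = 1990.0


class CoverageError(ValueError):
    """Raised when a recording does not cover a required analysis window."""


@dataclass
class ArtifactMask:
    """Window-resolution artifact mask with provenance.

    ``per_channel`` has shape (n_eeg_channels, n_windows); ``combined`` is
    the any-channel union — a window flagged on any EEG channel is excluded
    on all channels.
    """

    per_channel: np.ndarray
    window_s: float
    z_thresh: float
    channel_labels: list[str]

    @property
    def combined(self) -> np.ndarray:
        return self.per_channel.any(axis=0)

    @property
    def n_windows(self) -> int:
        return self.per_channel.shape[1]

    def sample_mask(self, n_samples: int, fs: float) -> np.ndarray:
        """Boolean per-sample mask (True = artifact) at the recording's rate."""
        idx = np.minimum(
            (np.arange(n_samples) / (self.window_s * fs)).astype(np.int64),
            self.n_windows - 1,
        )
        return self.combined[idx]

    def fraction_flagged(self) -> float:
        return float(self.combined.mean()) if self.n_windows else 0.0


def detect_artifacts(recording: Recording, window_s: float = 1.0,
                     z_thresh: float = 8.0) -> ArtifactMask:
    """Flag windows whose peak |amplitude| exceeds ``z_thresh`` robust z-units.

    The robust scale is median/MAD over the whole recording, per EEG
    channel; windows containing saturated samples are also flagged.  A flag
    on any EEG channel excludes the window globally (``combined``).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    fs = recording.sampling_rate
    wlen = int(round(window_s * fs))
    if recording.n_samples < wlen:
        raise ValueError(
            f"recording ({recording.n_samples} samples) shorter than one "
            f"{window_s} s window"
        )
    n_windows = int(np.ceil(recording.n_samples / wlen))
    eeg_idx = recording.eeg_indices()
    per_channel = np.zeros((len(eeg_idx), n_windows), dtype=bool)
    pad = n_windows * wlen - recording.n_samples
    for row, ch in enumerate(eeg_idx):
        x = recording.signals[ch]
        med = np.median(x)
        sigma = 1.4826 * np.median(np.abs(x - med))
        absx = np.pad(np.abs(x), (0, pad)).reshape(n_windows, wlen)
        dev = np.pad(np.abs(x - med), (0, pad)).reshape(n_windows, wlen)
        saturated = absx.max(axis=1) >= SATURATION_UV
        flagged = saturated
        if sigma > 0:
            flagged = flagged | (dev.max(axis=1) > z_thresh * sigma)
        per_channel[row] = flagged
    return ArtifactMask(
        per_channel=per_channel,
        window_s=window_s,
        z_thresh=z_thresh,
        channel_labels=[recording.channel_labels[i] for i in eeg_idx],
    )


def detrend_mean(x: np.ndarray) -> np.ndarray:
    """Subtract the mean; shape preserved, idempotent."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot detrend an empty signal")
    return x - x.mean(axis=-1, keepdims=True)


def design_notch(fs: float, center: float = 60.0, half_bw: float = 2.0,
                 order: int = 8) -> np.ndarray:
    """Butterworth band-stop SOS around ``center ± half_bw`` Hz."""
    if fs <= 2 * (center + half_bw):
        raise ValueError(
            f"sampling rate {fs} Hz too low for a notch at {center}±{half_bw} Hz"
        )
    sos = sps.butter(order, [center - half_bw, center + half_bw],
                     btype="bandstop", fs=fs, output="sos")
    _, poles, _ = sps.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError(
            f"unstable notch design at fs={fs} Hz (order {order}); "
            "reduce the order or widen the band"
        )
    return sos


def notch_filter(x: np.ndarray, fs: float, center: float = 60.0,
                 half_bw: float = 2.0, order: int = 8) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth band-stop filter.

    Designed as an order-``order`` band-stop in second-order sections and
    applied bidirectionally, so the effective magnitude response is squared
    and the net phase shift is zero.
    """
    sos = design_notch(fs, center, half_bw, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def preprocess_recording(recording: Recording, window_s: float = 1.0,
                         z_thresh: float = 8.0, center: float = 60.0,
                         half_bw: float = 2.0, order: int = 8
                         ) -> tuple[Recording, ArtifactMask]:
    """Fixed pipeline: artifact detection → detrend → notch, on EEG channels.

    EMG channels are detrended but not notch filtered.  Returns a new
    Recording plus the artifact mask (exclusion is applied downstream at
    Welch segmentation, not by zero-filling here).
    """
    mask = detect_artifacts(recording, window_s=window_s, z_thresh=z_thresh)
    out = recording.signals.copy()
    eeg = set(recording.eeg_indices())
    for ch in range(recording.n_channels):
        out[ch] = detrend_mean(out[ch])
        if ch in eeg:
            out[ch] = notch_filter(out[ch], recording.sampling_rate,
                                   center=center, half_bw=half_bw, order=order)
    rec = Recording(signals=out, sampling_rate=recording.sampling_rate,
                    channel_labels=list(recording.channel_labels),
                    start_time=recording.start_time)
    return rec, mask


#: Start hours (on the second calendar day) of the six analysis windows.
ANALYSIS_START_HOURS = (0, 4, 8, 12, 16, 20)


def select_analysis_hours(recording: Recording) -> list[tuple[float, float]]:
    """The six 1-hour analysis windows on the second recording day.

    Windows start at 12 AM, 4 AM, 8 AM, 12 PM, 4 PM and 8 PM of the second
    calendar day, resolved against the recording's start clock time; a
    partial first day is allowed as long as day 2 is fully covered.
    Returned as (start_s, end_s) in elapsed recording seconds.
    """
    start = recording.start_time
    day2 = _dt.datetime.combine(
        start.date() + _dt.timedelta(days=1), _dt.time(0, 0)
    )
    windows = []
    for h in ANALYSIS_START_HOURS:
        w0 = (day2 + _dt.timedelta(hours=h) - start).total_seconds()
        w1 = w0 + 3600.0
        if w0 < 0 or w1 > recording.duration_s + 1e-9:
            t = (day2 + _dt.timedelta(hours=h)).strftime("%Y-%m-%d %H:%M")
            raise CoverageError(
                f"recording ({recording.duration_s / 3600:.1f} h from "
                f"{start}) does not cover the analysis window starting {t}"
            )
        windows.append((w0, w1))
    return windows
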