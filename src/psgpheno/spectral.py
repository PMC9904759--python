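"""Welch PSD, notch-band interpolation, band powers, and the low/high ratio.

The biomarker computed here is the low- to high-frequency power ratio
(α + β1 + β2)/γ2 — the summed 8–25 Hz band power over the 50–100 Hz band
power.  Because it is a ratio of two integrals of the same PSD, it is
invariant to any positive rescaling of the spectrum, in particular to
normalization by total 1–100 Hz power (relative PSD).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ArtifactMask

#: The seven analysis bands (Hz), contiguous over 1–100.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "low_beta": (13.0, 18.0),
    "high_beta": (18.0, 25.0),
    "low_gamma": (25.0, 50.0),
    "high_gamma": (50.0, 100.0),
}

#: Bands whose summed power forms the ratio numerator (8–25 Hz).
RATIO_NUMERATOR = ("alpha", "low_beta", "high_beta")
RATIO_DENOMINATOR = "high_gamma"

TOTAL_RANGE = (1.0, 100.0)


class SpectralError(ValueError):
    """Raised for spectral-analysis contract violations."""


@dataclass
class PSDResult:
    """Welch PSD estimate on a uniform frequency grid.

    ``psd`` has shape (n_channels, n_freqs) in signal-units²/Hz.
    """

    freqs: np.ndarray
    psd: np.ndarray
    n_segments: int
    channel_labels: list[str]
    interpolated_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise SpectralError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise SpectralError("PSD values must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandPowerTable:
    """Absolute and relative band powers per channel, plus the ratio.

    ``absolute`` and ``relative`` are DataFrames indexed by channel label
    with one column per band; ``total_power`` is the 1–100 Hz integral and
    ``ratio_low_high`` the (α+β1+β2)/γ2 statistic, both per channel.
    """

    absolute: pd.DataFrame
    relative: pd.DataFrame
    total_power: pd.Series
    ratio_low_high: pd.Series


def _clean_segment_starts(n_samples: int, nperseg: int, step: int,
                          sample_mask: np.ndarray | None) -> np.ndarray:
    """Welch segment start indices, skipping any segment touching a mask.

    Segments are formed inside maximal artifact-free runs only; they never
    straddle masked windows.
    """
    if sample_mask is None:
        return np.arange(0, n_samples - nperseg + 1, step, dtype=np.int64)
    starts: list[int] = []
    clean = ~np.asarray(sample_mask, dtype=bool)
    # maximal clean runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], clean.view(np.int8), [0]])))
    for r0, r1 in zip(edges[::2], edges[1::2]):
        starts.extend(range(r0, r1 - nperseg + 1, step))
    return np.asarray(starts, dtype=np.int64)


def welch_psd(
    signals: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
    artifact_mask: ArtifactMask | None = None,
    channel_labels: Sequence[str] | None = None,
) -> PSDResult:
    """Welch PSD with a Hann window over artifact-free segments.

    With the default 2 s window the frequency grid spacing is exactly
    1/window_s = 0.5 Hz.  Segments overlap by ``overlap`` and are drawn only
    from maximal artifact-free runs; each segment is mean-detrended and
    Hann-tapered, and the one-sided density-scaled periodograms are
    averaged.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samples = signals.shape
    nperseg = int(round(window_s * fs))
    if not 0 <= overlap < 1:
        raise SpectralError("overlap must be in [0, 1)")
    step = max(int(round(nperseg * (1 - overlap))), 1)
    sample_mask = (
        artifact_mask.sample_mask(n_samples, fs) if artifact_mask is not None else None
    )
    starts = _clean_segment_starts(n_samples, nperseg, step, sample_mask)
    if len(starts) == 0:
        raise SpectralError(
            "no artifact-free segment of length "
            f"{window_s} s available for Welch estimation"
        )
    window = np.hanning(nperseg)
    scale = 1.0 / (fs * np.sum(window**2))
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    psd = np.empty((n_ch, len(freqs)))
    segs_idx = starts[:, None] + np.arange(nperseg)[None, :]
    for ch in range(n_ch):
        segs = signals[ch][segs_idx]
        segs = segs - segs.mean(axis=1, keepdims=True)
        spec = np.abs(np.fft.rfft(segs * window, axis=1)) ** 2
        pxx = spec.mean(axis=0) * scale
        pxx[1:] *= 2.0
        if nperseg % 2 == 0:
            pxx[-1] /= 2.0
        psd[ch] = pxx
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_ch)]
    return PSDResult(freqs=freqs, psd=psd, n_segments=len(starts),
                     channel_labels=list(channel_labels))


def interpolate_notch_band(
    psd_result: PSDResult,
    lo: float = 58.0,
    hi: float = 62.0,
    n_points: int = 10,
    method: str = "least_squares",
) -> PSDResult:
    """Replace PSD values in [lo, hi] by a line fitted to flanking points.

    ``method="least_squares"`` (default) fits one least-squares line through
    the ``n_points`` grid points immediately below ``lo`` and the
    ``n_points`` immediately above ``hi``.  ``method="flank_means"`` draws
    the line through the two flank mean points instead.  All values outside
    [lo, hi] are untouched.
    """
    freqs = psd_result.freqs
    in_band = (freqs >= lo) & (freqs <= hi)
    below = np.flatnonzero(freqs < lo)[-n_points:]
    above = np.flatnonzero(freqs > hi)[:n_points]
    if len(below) < n_points or len(above) < n_points:
        raise SpectralError(
            f"need {n_points} grid points on each side of [{lo}, {hi}] Hz"
        )
    flank_idx = np.concatenate([below, above])
    psd = psd_result.psd.copy()
    for ch in range(psd.shape[0]):
        fx, fy = freqs[flank_idx], psd[ch, flank_idx]
        if method == "least_squares":
            slope, intercept = np.polyfit(fx, fy, 1)
        elif method == "flank_means":
            x1, y1 = freqs[below].mean(), psd[ch, below].mean()
            x2, y2 = freqs[above].mean(), psd[ch, above].mean()
            slope = (y2 - y1) / (x2 - x1)
            intercept = y1 - slope * x1
        else:
            raise SpectralError(f"unknown interpolation method {method!r}")
        psd[ch, in_band] = np.clip(slope * freqs[in_band] + intercept, 0.0, None)
    return replace(psd_result, psd=psd, interpolated_range=(lo, hi))


def _band_slice(freqs: np.ndarray, lo: float, hi: float) -> slice:
    i0 = int(np.searchsorted(freqs, lo))
    i1 = int(np.searchsorted(freqs, hi))
    if i0 >= len(freqs) or abs(freqs[i0] - lo) > 1e-9 or i1 >= len(freqs) or abs(freqs[i1] - hi) > 1e-9:
        raise SpectralError(
            f"band edge ({lo}, {hi}) Hz off the {freqs[1]-freqs[0]:g} Hz grid"
        )
    return slice(i0, i1 + 1)


def band_powers(psd_result: PSDResult,
                bands: Mapping[str, tuple[float, float]] = BANDS) -> BandPowerTable:
    """Trapezoidal band powers, relative powers, and the low/high ratio.

    Absolute band power is the trapezoidal area under the PSD between the
    band edges (edges on-grid, both endpoints included).  Because the seven
    bands tile 1–100 Hz with shared edges, their absolute powers sum exactly
    to the 1–100 Hz total.  Relative power divides by that total.
    """
    freqs = psd_result.freqs
    rows_abs = {}
    for name, (lo, hi) in bands.items():
        sl = _band_slice(freqs, lo, hi)
        rows_abs[name] = np.trapezoid(psd_result.psd[:, sl], freqs[sl], axis=1)
    sl_tot = _band_slice(freqs, *TOTAL_RANGE)
    total = np.trapezoid(psd_result.psd[:, sl_tot], freqs[sl_tot], axis=1)
    if np.any(total <= 0):
        raise SpectralError(
            "zero total power in 1-100 Hz; relative powers undefined"
        )
    absolute = pd.DataFrame(rows_abs, index=psd_result.channel_labels)
    relative = absolute.div(total, axis=0)
    total_s = pd.Series(total, index=psd_result.channel_labels, name="total_1_100")
    num = absolute[list(RATIO_NUMERATOR)].sum(axis=1)
    den = absolute[RATIO_DENOMINATOR]
    if np.any(den.to_numpy() == 0):
        raise SpectralError("zero high-gamma power; ratio undefined")
    table = BandPowerTable(
        absolute=absolute,
        relative=relative,
        total_power=total_s,
        ratio_low_high=(num / den).rename("ratio_low_high"),
    )
    return table


def power_ratio(band_table: BandPowerTable, use_relative: bool = False) -> pd.Series:
    """The (α + β1 + β2)/γ2 ratio per channel.

    Identical whether computed from absolute or relative band powers, since
    the total-power normalization cancels.
    """
    powers = band_table.relative if use_relative else band_table.absolute
    den = powers[RATIO_DENOMINATOR]
    if np.any(den.to_numpy() == 0):
        raise SpectralError("zero high-gamma power; ratio undefined")
    return (powers[list(RATIO_NUMERATOR)].sum(axis=1) / den).rename("ratio_low_high")


def relative_psd(psd_result: PSDResult) -> PSDResult:
    """Normalize each channel's PSD by its total 1–100 Hz power.

    The output integrates to 1 over 1–100 Hz per channel.
    """
    sl = _band_slice(psd_result.freqs, *TOTAL_RANGE)
    total = np.trapezoid(psd_result.psd[:, sl], psd_result.freqs[sl], axis=1)
    if np.any(total <= 0):
        raise SpectralError("zero total power in 1-100 Hz; cannot normalize")
    return replace(psd_result, psd=psd_result.psd / total[:, None])


def band_power_frame(table: BandPowerTable, animal_id: str = "") -> pd.DataFrame:
    """Long-format frame (animal, channel, band, absolute, relative, ratio)."""
    rows = []
    for ch in table.absolute.index:
        for band in table.absolute.columns:
            rows.append({
                "animal_id": animal_id,
                "channel": ch,
                "band": band,
                "absolute_power": table.absolute.loc[ch, band],
                "relative_power": table.relative.loc[ch, band],
                "ratio_low_high": table.ratio_low_high.loc[ch],
            })
    return pd.DataFrame(rows)
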