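"""Sharp-transient detection and poly-spike episode clustering.

An episode of poly-spikes is a cluster of three or more spikes on any of
the EEG channels; spikes from all EEG channels are pooled before
clustering.  The detector operationalizes visual spike marking as a
robust-z amplitude threshold on a high-passed copy of the signal with a
half-amplitude-width criterion, so it is invariant to global amplitude
scaling and to channel ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording
from .preprocess import ArtifactMask

#: High-pass corner (Hz) for the detection copy of the signal.  On 1/f-type
#: backgrounds the raw robust-z is dominated by slow waves; the high-pass
#: makes the threshold refer to sharp-transient amplitude.
DETECT_HIGHPASS_HZ = 5.0


@dataclass
class SpikeEvent:
    """One detected sharp transient."""

    time_s: float
    channel: str
    amplitude_z: float
    width_ms: float


@dataclass
class PolyspikeEpisode:
    """A cluster of >=3 spikes (pooled across EEG channels)."""

    start_s: float
    end_s: float
    n_spikes: int
    channels: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_spikes < 3:
            raise ValueError("an episode requires at least 3 spikes")
        if self.end_s < self.start_s:
            raise ValueError("episode end before start")


def detect_spikes(
    recording: Recording,
    z_thresh: float = 6.0,
    width_ms: tuple[float, float] = (20.0, 70.0),
    refractory_ms: float = 30.0,
) -> list[SpikeEvent]:
    """Detect sharp transients on every EEG channel.

    A spike is a local extremum of the high-passed signal exceeding
    ``z_thresh`` robust z-units (median/MAD per channel) whose
    half-amplitude width lies inside ``width_ms``.  Extrema of either
    polarity are detected; events closer than ``refractory_ms`` on the same
    channel are merged, keeping the larger.
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    fs = recording.sampling_rate
    events: list[SpikeEvent] = []
    sos = sps.butter(4, DETECT_HIGHPASS_HZ, btype="highpass", fs=fs, output="sos")
    for ch in recording.eeg_indices():
        label = recording.channel_labels[ch]
        x = sps.sosfiltfilt(sos, recording.signals[ch])
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        sigma = 1.4826 * mad
        if sigma == 0:
            continue
        z = np.abs(x - med) / sigma
        min_w = max(int(width_ms[0] * fs / 1000.0 * 0.25), 1)
        peaks, props = sps.find_peaks(z, height=z_thresh, width=min_w,
                                      rel_height=0.5)
        widths_ms = props["widths"] / fs * 1000.0
        keep = (widths_ms >= width_ms[0]) & (widths_ms <= width_ms[1])
        ch_events = [
            SpikeEvent(time_s=float(p / fs), channel=label,
                       amplitude_z=float(z[p]), width_ms=float(w))
            for p, w in zip(peaks[keep], widths_ms[keep])
        ]
        events.extend(_merge_refractory(ch_events, refractory_ms))
    events.sort(key=lambda e: e.time_s)
    return events


def _merge_refractory(events: list[SpikeEvent], refractory_ms: float) -> list[SpikeEvent]:
    """Merge same-channel events closer than the refractory gap, keeping the larger."""
    out: list[SpikeEvent] = []
    for ev in sorted(events, key=lambda e: e.time_s):
        if out and (ev.time_s - out[-1].time_s) * 1000.0 < refractory_ms:
            if ev.amplitude_z > out[-1].amplitude_z:
                out[-1] = ev
        else:
            out.append(ev)
    return out


def cluster_episodes(
    spikes: list[SpikeEvent],
    max_gap_ms: float = 200.0,
    min_spikes: int = 3,
) -> list[PolyspikeEpisode]:
    """Single-linkage clustering of pooled spikes into episodes.

    Spikes (already pooled across channels) are grouped wherever consecutive
    inter-spike gaps are ≤ ``max_gap_ms``; groups of at least ``min_spikes``
    become episodes, smaller groups are discarded.
    """
    if not spikes:
        return []
    spikes = sorted(spikes, key=lambda e: e.time_s)
    episodes: list[PolyspikeEpisode] = []
    group: list[SpikeEvent] = [spikes[0]]
    for ev in spikes[1:]:
        if (ev.time_s - group[-1].time_s) * 1000.0 <= max_gap_ms:
            group.append(ev)
        else:
            if len(group) >= min_spikes:
                episodes.append(_make_episode(group))
            group = [ev]
    if len(group) >= min_spikes:
        episodes.append(_make_episode(group))
    return episodes


def _make_episode(group: list[SpikeEvent]) -> PolyspikeEpisode:
    return PolyspikeEpisode(
        start_s=group[0].time_s,
        end_s=group[-1].time_s,
        n_spikes=len(group),
        channels=frozenset(e.channel for e in group),
    )


def drop_artifact_episodes(
    episodes: list[PolyspikeEpisode],
    mask: ArtifactMask,
) -> list[PolyspikeEpisode]:
    """Discard episodes overlapping flagged artifact windows."""
    combined = mask.combined
    out = []
    for ep in episodes:
        w0 = int(ep.start_s // mask.window_s)
        w1 = int(ep.end_s // mask.window_s)
        w1 = min(w1, len(combined) - 1)
        if not combined[w0:w1 + 1].any():
            out.append(ep)
    return out


def episode_rate(
    episodes: list[PolyspikeEpisode],
    analysis_windows: list[tuple[float, float]],
) -> float:
    """Episodes per hour: episodes starting inside any window / total hours."""
    total_s = sum(e - s for s, e in analysis_windows)
    if total_s <= 0:
        raise ValueError("zero total analysis-window duration")
    count = sum(
        any(s <= ep.start_s < e for s, e in analysis_windows) for ep in episodes
    )
    return count / (total_s / 3600.0)
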