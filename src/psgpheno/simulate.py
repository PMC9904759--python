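"""Synthetic polysomnography: cohorts of EEG/EMG recordings with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes in a maternal-deletion mouse model treated with antisense
oligonucleotides:

* a semi-Markov wake/NREM/REM hypnogram at 4 s resolution with
  phase-dependent (light/dark) bout durations and a light-phase REM deficit
  that scales with the loss of UBE3A protein;
* per-state 1/f^χ EEG spectra (NREM δ boost, REM θ peak, broadband wake)
  with a genotype effect that multiplies 8–25 Hz power by
  ``1 + band_effect_low·(1 − protein_level)`` and 50–100 Hz power by
  ``1 − band_effect_high·(1 − protein_level)``;
* EMG with RMS ordering wake > NREM > REM;
* 60 Hz line noise, amplitude artifacts, and Poisson-distributed poly-spike
  episodes of ≥3 sharp transients;
* covariates: genotype, UBE3A protein level (fraction of wild type), and an
  antisense-transcript (ATS) level generated as the inverse of a one-phase
  exponential decay so the association stage has a recoverable target.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    EventList,
    Hypnogram,
    Recording,
    write_events,
    write_hypnogram,
    write_recording,
)

#: EDF channel labels: left frontal, left somatosensory, right visual, neck EMG.
EEG_LABELS = ("EEG FC-L", "EEG SC-L", "EEG VC-R")
EMG_LABEL = "EMG"

#: Per-state EEG standard deviation, µV.
EEG_SIGMA = {"WAKE": 45.0, "NREM": 80.0, "REM": 40.0}
#: Per-state EMG RMS, µV; ordering wake > NREM > REM (atonia) by construction.
EMG_RMS = {"WAKE": 60.0, "NREM": 18.0, "REM": 5.0}

#: One-phase decay linking protein to antisense transcript: p = a·e^(−k·ATS) + b.
ATS_DECAY = {"a": 1.0, "k": 1.2, "b": 0.0}

_DEFAULT_DWELL = {
    # mean bout duration in seconds, (light, dark)
    "WAKE": (120.0, 400.0),
    "NREM": (300.0, 180.0),
    "REM": (90.0, 70.0),
}

#: Embedded-chain transition probabilities; REM is entered only from NREM.
_TRANSITIONS = {
    "WAKE": {"NREM": 1.0},
    "NREM": {"WAKE": 0.65, "REM": 0.35},
    "REM": {"WAKE": 0.8, "NREM": 0.2},
}

_GAMMA_SHAPE = 2.0  # bout-length gamma shape; avoids unrealistically short bouts


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Configuration of one synthetic recording.

    ``protein_level`` is the UBE3A protein level as a fraction of wild type;
    1.0 is a wild-type animal and 0.0 a full maternal deletion.  All mutant
    effect sizes scale linearly with ``1 − protein_level``.
    """

    sampling_rate: float = 5000.0
    duration_h: float = 48.0
    n_eeg_channels: int = 3
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2023, 1, 2, 0, 0, 0)
    )
    lights_on: str = "06:00"
    light_hours: float = 14.0
    state_dwell_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DWELL)
    )
    spectral_exponent: float = 2.0
    band_effect_low: float = 0.3
    band_effect_high: float = 0.4
    rem_reduction_light: float = 0.4
    spike_rate: float = 12.0
    # below the gross-artifact amplitude criterion: epileptiform transients
    # are large but not movement-artifact large
    spike_amplitude_z: float = 5.0
    line_noise_amp: float = 5.0
    artifact_rate: float = 2.0
    artifact_amp: float = 800.0
    protein_level: float = 1.0
    epoch_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ConfigError("duration must be positive")
        if not (0 <= self.rem_reduction_light < 1):
            raise ConfigError("rem_reduction_light must be in [0, 1)")
        if not (0 <= self.protein_level <= 1):
            raise ConfigError("protein_level must be in [0, 1]")
        if not (0 < self.light_hours < 24):
            raise ConfigError("light_hours must be in (0, 24)")
        for rate in (self.spike_rate, self.artifact_rate, self.line_noise_amp):
            if rate < 0:
                raise ConfigError("rates and amplitudes must be >= 0")
        for state, (ml, md) in self.state_dwell_means.items():
            if ml <= 0 or md <= 0:
                raise ConfigError(f"non-positive dwell mean for state {state}")

    @property
    def duration_s(self) -> float:
        return self.duration_h * 3600.0

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // self.epoch_s)

    def lights_on_hour(self) -> float:
        hh, mm = self.lights_on.split(":")
        return int(hh) + int(mm) / 60.0


@dataclass
class GroundTruth:
    """Simulator sidecar: what was actually injected."""

    state_sequence: Hypnogram
    spike_episode_times: list[float] = field(default_factory=list)
    spike_episode_counts: list[int] = field(default_factory=list)
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)
    covariates: dict = field(default_factory=dict)


def _is_light(t_s: np.ndarray | float, config: SimConfig) -> np.ndarray | bool:
    """Light/dark phase of elapsed recording time(s) ``t_s``."""
    start_h = (
        config.start_time.hour
        + config.start_time.minute / 60.0
        + config.start_time.second / 3600.0
    )
    clock = (start_h + np.asarray(t_s) / 3600.0) % 24.0
    rel = (clock - config.lights_on_hour()) % 24.0
    return rel < config.light_hours


def _rem_scale(config: SimConfig) -> float:
    return 1.0 - config.rem_reduction_light * (1.0 - config.protein_level)


def simulate_hypnogram(config: SimConfig,
                       rng: np.random.Generator | None = None) -> Hypnogram:
    """Simulate a semi-Markov wake/NREM/REM sequence at 4 s epochs.

    Bout durations are gamma-distributed (shape 2) with phase-dependent
    means; REM is entered only from NREM.  In the light phase the REM
    dwell mean is scaled by ``1 − rem_reduction_light·(1 − protein_level)``,
    producing the mutant light-phase REM occupancy deficit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = 0.0
    state = "WAKE"
    bounds: list[float] = [0.0]
    states: list[str] = []
    total = config.duration_s
    while t < total:
        light = bool(_is_light(t, config))
        mean = config.state_dwell_means[state][0 if light else 1]
        if state == "REM" and light:
            mean *= _rem_scale(config)
        dwell = rng.gamma(_GAMMA_SHAPE, mean / _GAMMA_SHAPE)
        t += dwell
        states.append(state)
        bounds.append(min(t, total))
        probs = _TRANSITIONS[state]
        state = rng.choice(list(probs), p=list(probs.values()))
    edges = np.asarray(bounds)
    epoch_mid = (np.arange(config.n_epochs) + 0.5) * config.epoch_s
    idx = np.searchsorted(edges, epoch_mid, side="right") - 1
    labels = [states[i] for i in np.clip(idx, 0, len(states) - 1)]
    return Hypnogram(labels=labels, epoch_s=config.epoch_s,
                     start_time=config.start_time)


def _state_spectrum(freqs: np.ndarray, state: str, config: SimConfig) -> np.ndarray:
    """Target power spectrum (arbitrary scale) for one state."""
    f0 = 1.0  # knee keeps the DC-adjacent bins finite
    base = 1.0 / (freqs + f0) ** config.spectral_exponent
    shape = np.ones_like(freqs)
    if state == "NREM":
        shape += 4.0 * np.exp(-0.5 * ((freqs - 2.5) / 1.2) ** 2)
    elif state == "REM":
        shape += 3.0 * np.exp(-0.5 * ((freqs - 6.5) / 1.0) ** 2)
        shape -= 0.5 * np.exp(-0.5 * ((freqs - 2.0) / 1.0) ** 2)
    else:  # WAKE: mild broadband high-frequency lift
        shape += 0.8 * np.exp(-0.5 * ((freqs - 30.0) / 20.0) ** 2)
    spec = base * np.clip(shape, 0.05, None)
    deficit = 1.0 - config.protein_level
    mult = np.ones_like(freqs)
    low = (freqs >= 8.0) & (freqs < 25.0)
    mid = (freqs >= 25.0) & (freqs < 50.0)
    high = (freqs >= 50.0) & (freqs <= 100.0)
    mult[low] = 1.0 + config.band_effect_low * deficit
    mult[high] = 1.0 - config.band_effect_high * deficit
    # keep total 1-100 Hz power fixed by absorbing the imbalance in 25-50 Hz:
    # the unmanipulated delta/theta share of the spectrum is then untouched
    # in relative terms, as observed in the phenotype being emulated.
    if deficit > 0 and mid.sum() >= 2:
        p_low = np.trapezoid(spec[low], freqs[low]) if low.sum() >= 2 else 0.0
        p_high = np.trapezoid(spec[high], freqs[high]) if high.sum() >= 2 else 0.0
        p_mid = np.trapezoid(spec[mid], freqs[mid])
        if p_mid > 0:
            imbalance = (config.band_effect_low * deficit * p_low
                         - config.band_effect_high * deficit * p_high)
            mult[mid] = np.clip(1.0 - imbalance / p_mid, 0.1, None)
    spec = spec * mult
    spec[freqs == 0] = 0.0
    return spec


def _colored_noise(n: int, fs: float, spectrum, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with target power spectrum, unit variance."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.sqrt(spectrum(freqs))
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * amp, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_signals(
    hypnogram: Hypnogram,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Recording, GroundTruth]:
    """Render EEG/EMG signals for a hypnogram.

    Each state bout is synthesized independently by FFT-shaping white noise
    to the state's target spectrum (so phase structure is realistic), then
    scaled to the state's RMS.  Line noise and amplitude artifacts are added
    afterwards; poly-spikes are injected by :func:`inject_polyspikes`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fs = config.sampling_rate
    n_total = int(round(hypnogram.duration_s * fs))
    labels = hypnogram.as_array()
    n_eeg = config.n_eeg_channels
    eeg = np.empty((n_eeg, n_total))
    emg = np.empty(n_total)

    # contiguous state runs
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [len(labels)]])
    spe = int(round(hypnogram.epoch_s * fs))
    for s, e in zip(run_starts, run_ends):
        state = labels[s]
        i0, i1 = s * spe, min(e * spe, n_total)
        n = i1 - i0
        if n <= 0:
            continue
        for ch in range(n_eeg):
            x = _colored_noise(n, fs, lambda f: _state_spectrum(f, state, config), rng)
            eeg[ch, i0:i1] = EEG_SIGMA[state] * x
        emg[i0:i1] = EMG_RMS[state] * rng.standard_normal(n)

    t = np.arange(n_total) / fs
    if config.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        eeg += config.line_noise_amp * np.sin(2 * np.pi * 60.0 * t + phase)

    truth = GroundTruth(
        state_sequence=hypnogram,
        covariates=make_covariates(config, rng),
    )
    # amplitude artifacts: large slow excursions on all EEG channels
    n_art = rng.poisson(config.artifact_rate * hypnogram.duration_s / 3600.0)
    for _ in range(n_art):
        dur = rng.uniform(0.5, 3.0)
        onset = rng.uniform(0, max(hypnogram.duration_s - dur, 0))
        i0 = int(onset * fs)
        n = int(dur * fs)
        burst = config.artifact_amp * np.sin(np.pi * np.arange(n) / n)
        eeg[:, i0:i0 + n] += burst[: eeg.shape[1] - i0]
        truth.artifact_intervals.append((onset, onset + dur))
    truth.artifact_intervals = merge_intervals(truth.artifact_intervals)

    signals = np.vstack([eeg, emg[None, :]])
    labels_out = list(EEG_LABELS[:n_eeg])
    labels_out += [f"EEG X{i}" for i in range(len(labels_out), n_eeg)]
    labels_out.append(EMG_LABEL)
    rec = Recording(
        signals=signals,
        sampling_rate=fs,
        channel_labels=labels_out,
        start_time=hypnogram.start_time or config.start_time,
    )
    return rec, truth


def merge_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping (start, end) intervals."""
    out: list[tuple[float, float]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def make_covariates(config: SimConfig, rng: np.random.Generator) -> dict:
    """Genotype/protein/ATS covariates for one animal.

    ATS level is the inverse of the one-phase decay
    ``protein = a·e^(−k·ATS) + b`` (with multiplicative noise), so that
    fitting the decay to (ATS, protein) pairs recovers the generating
    constants.
    """
    p = config.protein_level
    a, k, b = ATS_DECAY["a"], ATS_DECAY["k"], ATS_DECAY["b"]
    p_eff = max(p, 0.02)
    ats = -np.log((p_eff - b) / a) / k
    ats *= float(np.exp(rng.normal(0.0, 0.05)))
    return {
        "genotype": "WT" if p >= 1.0 else "mutant",
        "protein_level": float(p),
        "ATS_level": float(ats),
    }


# ---------------------------------------------------------------------------
# Poly-spike injection
# ---------------------------------------------------------------------------

def sample_episode_onsets(rate_per_h: float, duration_s: float,
                          rng: np.random.Generator,
                          margin_s: float = 2.0) -> np.ndarray:
    """Poisson episode onsets, kept ``margin_s`` clear of the recording end."""
    if rate_per_h < 0:
        raise ConfigError("spike rate must be >= 0")
    n = rng.poisson(rate_per_h * duration_s / 3600.0)
    lo, hi = margin_s, max(duration_s - margin_s, margin_s)
    return np.sort(rng.uniform(lo, hi, size=n))


def _spike_wave(width_s: float, fs: float) -> np.ndarray:
    """A biphasic sharp transient (Ricker wavelet), unit peak amplitude.

    ``width_s`` is the half-amplitude width of the positive lobe.
    """
    # Ricker: (1 - (t/s)^2) exp(-t^2 / (2 s^2)); positive-lobe FWHM ≈ 1.25 s
    s = width_s / 1.25
    half = int(round(4 * s * fs))
    t = np.arange(-half, half + 1) / fs
    u = (t / s) ** 2
    return (1 - u) * np.exp(-u / 2)


def inject_polyspikes(
    recording: Recording,
    rate_per_h: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> tuple[Recording, GroundTruth]:
    """Inject Poisson-distributed poly-spike episodes into the recording.

    Each episode is a run of ≥3 stereotyped biphasic transients
    (half-amplitude width 20–70 ms, inter-spike gap ≤ 200 ms) on the first
    EEG channel, with amplitude ``spike_amplitude_z`` robust z-units above
    background.  The input recording is not mutated.  Injected episode
    onsets and spike counts are recorded in the returned ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if truth is None:
        truth = GroundTruth(
            state_sequence=Hypnogram(labels=[], epoch_s=config.epoch_s)
        )
    fs = recording.sampling_rate
    signals = recording.signals.copy()
    ch = recording.eeg_indices()[0]
    x = signals[ch]
    mad = np.median(np.abs(x - np.median(x)))
    robust_sigma = 1.4826 * mad if mad > 0 else (x.std() or 1.0)
    amp = config.spike_amplitude_z * robust_sigma

    onsets = sample_episode_onsets(rate_per_h, recording.duration_s, rng)
    kept: list[float] = []
    counts: list[int] = []
    last_end = -np.inf
    for onset in onsets:
        n_spikes = 3 + int(rng.poisson(1.5))
        gaps = rng.uniform(0.08, 0.18, size=n_spikes - 1)
        times = onset + np.concatenate([[0.0], np.cumsum(gaps)])
        if times[0] <= last_end + 1.0:  # skip overlapping/adjacent episodes
            continue
        if times[-1] + 0.1 >= recording.duration_s:
            continue
        for st in times:
            width = rng.uniform(0.025, 0.06)
            wave = _spike_wave(width, fs) * amp * rng.uniform(0.9, 1.1)
            i0 = int(round(st * fs)) - (len(wave) // 2)
            a, b = max(i0, 0), min(i0 + len(wave), signals.shape[1])
            signals[ch, a:b] += wave[a - i0: b - i0]
        kept.append(float(times[0]))
        counts.append(n_spikes)
        last_end = times[-1]
    truth.spike_episode_times = kept
    truth.spike_episode_counts = counts
    rec = Recording(
        signals=signals,
        sampling_rate=fs,
        channel_labels=list(recording.channel_labels),
        start_time=recording.start_time,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_animal(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """One animal end-to-end: hypnogram → signals → poly-spikes.

    The effective poly-spike rate is ``spike_rate·(1 − protein_level)``:
    wild-type animals show essentially none, full mutants the configured
    rate, matching the cortical-hyperexcitability phenotype.
    """
    rng = np.random.default_rng(config.seed)
    hyp = simulate_hypnogram(config, rng)
    rec, truth = synthesize_signals(hyp, config, rng)
    rate = config.spike_rate * (1.0 - config.protein_level)
    rec, truth = inject_polyspikes(rec, rate, config, rng, truth)
    return rec, truth


def _truth_events(truth: GroundTruth) -> EventList:
    rows = [
        {"onset_s": t, "duration_s": 0.0, "type": "polyspike", "channel": EEG_LABELS[0]}
        for t in truth.spike_episode_times
    ]
    rows += [
        {"onset_s": s, "duration_s": e - s, "type": "artifact", "channel": "all"}
        for s, e in truth.artifact_intervals
    ]
    return EventList(events=pd.DataFrame(rows, columns=["onset_s", "duration_s", "type", "channel"]))


def simulate_cohort(
    group_specs: Sequence[tuple[str, str, int, float]],
    config: SimConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Simulate a cohort and write one EDF plus sidecars per animal.

    ``group_specs`` is a list of ``(genotype, treatment, n, protein_level)``.
    Per-animal seeds derive deterministically from the master seed and the
    animal index.  Returns the manifest, which is also written to
    ``manifest.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    index = 0
    for genotype, treatment, n, protein in group_specs:
        if n < 1:
            raise ConfigError(f"group ({genotype},{treatment}) has n={n} < 1")
        for _ in range(n):
            animal_id = f"{genotype}_{treatment}_{index:03d}"
            seed = int((config.seed * 100003 + index * 7919 + 1) % (2**31 - 1))
            acfg = replace(config, protein_level=float(protein), seed=seed)
            rec, truth = simulate_animal(acfg)
            truth.covariates.update({"genotype": genotype, "treatment": treatment,
                                     "animal_id": animal_id})
            edf = out_dir / f"{animal_id}.edf"
            if edf.exists():
                raise FileExistsError(f"output path collision: {edf}")
            write_recording(rec, edf)
            write_hypnogram(truth.state_sequence, out_dir / f"{animal_id}_hypnogram.csv")
            write_events(_truth_events(truth), out_dir / f"{animal_id}_events.csv")
            with open(out_dir / f"{animal_id}_covariates.json", "w") as fh:
                json.dump(truth.covariates, fh, indent=2, sort_keys=True)
            rows.append({
                "animal_id": animal_id,
                "edf": edf.name,
                "genotype": genotype,
                "treatment": treatment,
                "protein_level": float(protein),
                "ATS_level": truth.covariates["ATS_level"],
                "seed": seed,
            })
            index += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
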