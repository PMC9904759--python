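"""Sleep staging, light/dark time budgets, and scorer-agreement metrics.

The stager is a transparent stand-in for CNN-based scorers: per 4 s epoch
it extracts spectral/EMG features, fits a 3-component Gaussian model on
(log EMG RMS, log θ/δ, log δ), identifies the components with wake, NREM
and REM by their feature signatures, and decodes the most probable state
path under a transition matrix that forbids direct wake→REM transitions.
Externally produced hypnograms (e.g. from a CNN scorer) enter through the
hypnogram CSV and feed the identical budget/agreement computations.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from sklearn.mixture import GaussianMixture

from .io import Hypnogram, Recording
from .spectral import welch_psd

_SLEEP_STATES = ("WAKE", "NREM", "REM")


class StagingError(ValueError):
    """Raised when epoch features cannot support staging."""


def extract_epoch_features(recording: Recording, epoch_s: float = 4.0) -> pd.DataFrame:
    """Per-epoch spectral and EMG features.

    One row per complete epoch (a trailing partial epoch is dropped) with
    columns ``delta``, ``theta``, ``theta_delta_ratio``, ``broadband``
    (EEG band powers, averaged over EEG channels) and ``emg_rms``.
    """
    fs = recording.sampling_rate
    spe = int(round(epoch_s * fs))
    n_epochs = recording.n_samples // spe
    if n_epochs == 0:
        raise StagingError(
            f"recording shorter than one {epoch_s} s epoch"
        )
    eeg_idx = recording.eeg_indices()
    emg_idx = [i for i in range(recording.n_channels) if i not in eeg_idx]
    nper = min(int(2 * fs), spe)
    win = np.hanning(nper)
    scale = 1.0 / (fs * np.sum(win**2))
    step = nper // 2

    def epoch_psd(sig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        epochs = sig[: n_epochs * spe].reshape(n_epochs, spe)
        starts = np.arange(0, spe - nper + 1, step)
        segs = epochs[:, starts[:, None] + np.arange(nper)[None, :]]
        segs = segs - segs.mean(axis=2, keepdims=True)
        spec = np.abs(np.fft.rfft(segs * win, axis=2)) ** 2
        pxx = spec.mean(axis=1) * scale
        pxx[:, 1:] *= 2.0
        if nper % 2 == 0:
            pxx[:, -1] /= 2.0
        return np.fft.rfftfreq(nper, 1.0 / fs), pxx

    delta = theta = broad = None
    for ch in eeg_idx:
        freqs, pxx = epoch_psd(recording.signals[ch])
        def bp(lo: float, hi: float) -> np.ndarray:
            m = (freqs >= lo) & (freqs <= hi)
            return np.trapezoid(pxx[:, m], freqs[m], axis=1)
        d = bp(1.0, 4.0)
        t = bp(4.0, 8.0)
        b = bp(1.0, min(100.0, fs / 2))
        delta = d if delta is None else delta + d
        theta = t if theta is None else theta + t
        broad = b if broad is None else broad + b
    n = len(eeg_idx)
    delta, theta, broad = delta / n, theta / n, broad / n

    if emg_idx:
        emg = recording.signals[emg_idx[0]][: n_epochs * spe].reshape(n_epochs, spe)
        emg_rms = np.sqrt(np.mean(emg**2, axis=1))
    else:
        emg_rms = np.zeros(n_epochs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / np.where(delta > 0, delta, 1.0), 0.0)
    return pd.DataFrame({
        "delta": delta,
        "theta": theta,
        "theta_delta_ratio": ratio,
        "broadband": broad,
        "emg_rms": emg_rms,
    })


@dataclass
class SleepStager:
    """Gaussian-emission sleep stager with Markov smoothing.

    A 3-component Gaussian mixture is fitted to (log EMG RMS, log θ/δ,
    log δ); the component with the highest mean log EMG is wake, and of the
    remaining two the one with higher mean log θ/δ is REM.  Decoding runs
    most-probable-path (Viterbi) smoothing under a fixed transition matrix
    with zero probability for wake→REM, the transition that does not occur
    in rodent sleep physiology.

    Attributes ending in ``_`` are set by :meth:`fit`.
    """

    self_transition: float = 0.97
    random_state: int = 0
    means_: np.ndarray = field(default=None, repr=False)
    covars_: np.ndarray = field(default=None, repr=False)
    state_order_: list[str] = field(default=None, repr=False)

    @staticmethod
    def _design(features: pd.DataFrame) -> np.ndarray:
        eps = 1e-12
        X = np.column_stack([
            np.log(features["emg_rms"].to_numpy() + eps),
            np.log(features["theta_delta_ratio"].to_numpy() + eps),
            np.log(features["delta"].to_numpy() + eps),
        ])
        return X

    def fit(self, features: pd.DataFrame) -> "SleepStager":
        X = self._design(features)
        if np.allclose(X.std(axis=0), 0):
            raise StagingError("degenerate features: no variation across epochs")
        gm = GaussianMixture(n_components=3, covariance_type="full",
                             n_init=3, random_state=self.random_state)
        gm.fit(X)
        means = gm.means_
        # component -> state by feature signature.  Highest mean log EMG is
        # wake; components within 0.5 nats of it are also wake (a recording
        # with little sleep splits wake across components).  Of the sleeping
        # components, the one with higher mean log θ/δ is REM when two
        # remain; a lone sleeping component is REM only if θ dominates δ.
        wake = int(np.argmax(means[:, 0]))
        labels = [None, None, None]
        for c in range(3):
            if means[c, 0] >= means[wake, 0] - 0.5:
                labels[c] = "WAKE"
        rest = [c for c in range(3) if labels[c] is None]
        if len(rest) == 2:
            rem = rest[int(np.argmax(means[rest, 1]))]
            for c in rest:
                labels[c] = "REM" if c == rem else "NREM"
        elif len(rest) == 1:
            labels[rest[0]] = "REM" if means[rest[0], 1] > 0 else "NREM"
        self.means_ = means
        self.covars_ = gm.covariances_
        self.state_order_ = labels
        return self

    def _hmm(self) -> GaussianHMM:
        p = self.self_transition
        q = 1.0 - p
        # label-level dynamics; WAKE -> REM forbidden
        t_lab = {
            ("WAKE", "WAKE"): p, ("WAKE", "NREM"): q, ("WAKE", "REM"): 0.0,
            ("NREM", "WAKE"): q * 0.6, ("NREM", "NREM"): p, ("NREM", "REM"): q * 0.4,
            ("REM", "WAKE"): q * 0.5, ("REM", "NREM"): q * 0.5, ("REM", "REM"): p,
        }
        start_lab = {"WAKE": 0.8, "NREM": 0.15, "REM": 0.05}
        labels = self.state_order_
        transmat = np.array([[t_lab[(li, lj)] for lj in labels] for li in labels])
        transmat /= transmat.sum(axis=1, keepdims=True)
        startprob = np.array([start_lab[lb] for lb in labels])
        startprob /= startprob.sum()
        hmm = GaussianHMM(n_components=3, covariance_type="full", init_params="")
        hmm.startprob_ = startprob
        hmm.transmat_ = transmat
        hmm.means_ = self.means_
        hmm.covars_ = self.covars_
        return hmm

    def predict(self, features: pd.DataFrame, epoch_s: float = 4.0,
                start_time: _dt.datetime | None = None) -> Hypnogram:
        if self.means_ is None:
            raise StagingError("SleepStager is not fitted")
        X = self._design(features)
        states = self._hmm().predict(X)
        labels = [self.state_order_[s] for s in states]
        return Hypnogram(labels=labels, epoch_s=epoch_s, start_time=start_time)

    def predict_raw(self, features: pd.DataFrame) -> np.ndarray:
        """Per-epoch argmax labels without Markov smoothing (diagnostic)."""
        if self.means_ is None:
            raise StagingError("SleepStager is not fitted")
        X = self._design(features)
        hmm = self._hmm()
        # emission log-likelihoods only
        ll = hmm._compute_log_likelihood(X)
        return np.asarray(self.state_order_, dtype=object)[np.argmax(ll, axis=1)]


def classify_epochs(features: pd.DataFrame, epoch_s: float = 4.0,
                    start_time: _dt.datetime | None = None,
                    random_state: int = 0) -> Hypnogram:
    """Fit a :class:`SleepStager` on the features and decode them."""
    stager = SleepStager(random_state=random_state).fit(features)
    return stager.predict(features, epoch_s=epoch_s, start_time=start_time)


# ---------------------------------------------------------------------------
# Time budgets
# ---------------------------------------------------------------------------

@dataclass
class SleepBudget:
    """Cumulative seconds per state per light/dark phase over 24 h."""

    seconds: dict  # (state, phase) -> float
    light_hours: float

    def get(self, state: str, phase: str) -> float:
        return self.seconds.get((state, phase), 0.0)

    def total(self, phase: str) -> float:
        return sum(v for (s, p), v in self.seconds.items() if p == phase)

    def minutes(self, state: str, phase: str) -> float:
        return self.get(state, phase) / 60.0


def time_budget(
    hypnogram: Hypnogram,
    start_time: _dt.datetime,
    lights_on: str = "06:00",
    light_hours: float = 14.0,
) -> SleepBudget:
    """24 h per-state time budget split by light/dark phase.

    If the hypnogram covers the second calendar day after ``start_time``
    (midnight to midnight), that day is scored, matching whole-second-day
    scoring; otherwise an exactly-24 h hypnogram is scored as given.
    Per phase, the per-state seconds (including artifact epochs) sum to the
    phase duration; light + dark = 24 h exactly.
    """
    epoch_s = hypnogram.epoch_s
    n_per_day = int(round(24 * 3600 / epoch_s))
    day2 = _dt.datetime.combine(start_time.date() + _dt.timedelta(days=1),
                                _dt.time(0, 0))
    offset_s = (day2 - start_time).total_seconds()
    first_epoch = int(round(offset_s / epoch_s))
    if first_epoch >= 0 and len(hypnogram) >= first_epoch + n_per_day:
        sel = slice(first_epoch, first_epoch + n_per_day)
        day_start = day2
    elif len(hypnogram) * epoch_s >= 24 * 3600:
        sel = slice(0, n_per_day)
        day_start = start_time
    else:
        raise ValueError(
            f"hypnogram spans {len(hypnogram) * epoch_s / 3600:.1f} h; "
            "a full 24 h day is required"
        )
    labels = np.asarray(hypnogram.labels, dtype=object)[sel]
    hh, mm = (int(v) for v in lights_on.split(":"))
    lights_on_h = hh + mm / 60.0
    start_h = day_start.hour + day_start.minute / 60.0 + day_start.second / 3600.0
    mid = (np.arange(n_per_day) + 0.5) * epoch_s / 3600.0
    clock = (start_h + mid) % 24.0
    is_light = ((clock - lights_on_h) % 24.0) < light_hours
    seconds: dict[tuple[str, str], float] = {}
    for state in ("WAKE", "NREM", "REM", "ARTIFACT"):
        for phase, msk in (("light", is_light), ("dark", ~is_light)):
            seconds[(state, phase)] = float(np.sum((labels == state) & msk) * epoch_s)
    return SleepBudget(seconds=seconds, light_hours=light_hours)


# ---------------------------------------------------------------------------
# Agreement metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a single state."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AgreementMetrics:
    """Precision/recall/F1/accuracy for one state, one scorer pair.

    Metrics with zero denominators are NaN, with the reason recorded in
    ``undefined`` — never silently zero.
    """

    precision: float
    recall: float
    f1: float
    accuracy: float
    counts: ConfusionCounts
    undefined: dict = field(default_factory=dict)


def confusion_counts(labels_a, labels_b, state: str,
                     exclude_artifact: bool = True) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``labels_a`` as reference."""
    a = np.asarray(list(labels_a), dtype=object)
    b = np.asarray(list(labels_b), dtype=object)
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    if exclude_artifact:
        keep = (a != "ARTIFACT") & (b != "ARTIFACT")
        a, b = a[keep], b[keep]
    pa, pb = a == state, b == state
    return ConfusionCounts(
        tp=int(np.sum(pa & pb)),
        fp=int(np.sum(~pa & pb)),
        fn=int(np.sum(pa & ~pb)),
        tn=int(np.sum(~pa & ~pb)),
    )


def agreement_metrics(labels_a, labels_b, state: str) -> AgreementMetrics:
    """Pairwise scorer agreement for one state.

    Precision = TP/(TP+FP); Recall = TP/(TP+FN);
    F1 = 2·Precision·Recall/(Precision+Recall);
    Accuracy = (TP+TN)/(TP+TN+FP+FN).  Epochs labelled ARTIFACT by either
    scorer are excluded from the counts.
    """
    if isinstance(labels_a, Hypnogram):
        labels_a = labels_a.labels
    if isinstance(labels_b, Hypnogram):
        labels_b = labels_b.labels
    c = confusion_counts(labels_a, labels_b, state)
    undefined: dict[str, str] = {}
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision = math.nan
        undefined["precision"] = "no epochs predicted as state (TP+FP=0)"
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = math.nan
        undefined["recall"] = "state absent from reference (TP+FN=0)"
    if not math.isnan(precision) and not math.isnan(recall) and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = math.nan
        undefined.setdefault("f1", "precision+recall undefined or zero")
    accuracy = (c.tp + c.tn) / c.total if c.total > 0 else math.nan
    if c.total == 0:
        undefined["accuracy"] = "no scorable epochs"
    return AgreementMetrics(precision=precision, recall=recall, f1=f1,
                            accuracy=accuracy, counts=c, undefined=undefined)
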