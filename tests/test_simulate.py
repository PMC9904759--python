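"""Synthetic-data generator: determinism, occupancy, effects, injection."""

import numpy as np
import pytest

from psgpheno import sleep, spectral
from psgpheno.simulate import (
    ConfigError,
    SimConfig,
    inject_polyspikes,
    sample_episode_onsets,
    simulate_animal,
    simulate_cohort,
    simulate_hypnogram,
    synthesize_signals,
)

FS = 500.0


def _flat_phase_config(**kw):
    """Same dwell means in both phases, so the chain is homogeneous."""
    dwell = {"WAKE": (120.0, 120.0), "NREM": (300.0, 300.0), "REM": (90.0, 90.0)}
    kw.setdefault("state_dwell_means", dwell)
    kw.setdefault("sampling_rate", FS)
    return SimConfig(**kw)


class TestHypnogram:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(sampling_rate=FS, duration_h=6, seed=5)
        assert simulate_hypnogram(cfg).labels == simulate_hypnogram(cfg).labels

    def test_rem_entered_only_from_nrem(self):
        cfg = SimConfig(sampling_rate=FS, duration_h=48, seed=3)
        labels = np.asarray(simulate_hypnogram(cfg).labels, dtype=object)
        prev = labels[np.flatnonzero((labels[1:] == "REM") & (labels[:-1] != "REM"))]
        assert set(prev) <= {"NREM"}

    def test_rem_occupancy_matches_longrun_oracle(self):
        """24 h empirical REM fraction sits within ±2 s.e. of the
        stationary fraction estimated by a brute-force 10x-duration run."""
        cfg = _flat_phase_config(duration_h=24, seed=0, protein_level=1.0)
        oracle_cfg = _flat_phase_config(duration_h=240, seed=999, protein_level=1.0)
        oracle_labels = np.asarray(simulate_hypnogram(oracle_cfg).labels, dtype=object)
        stationary = float(np.mean(oracle_labels == "REM"))
        fracs = []
        for seed in range(8):
            cfg_s = _flat_phase_config(duration_h=24, seed=seed, protein_level=1.0)
            labels = np.asarray(simulate_hypnogram(cfg_s).labels, dtype=object)
            fracs.append(float(np.mean(labels == "REM")))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - stationary) <= 2 * se + 1e-3

    def test_mutant_light_phase_rem_reduced(self):
        """Mean light-phase REM minutes lower in the mutant over 20 seeds."""
        def light_rem(p, seed):
            cfg = SimConfig(sampling_rate=FS, duration_h=48, seed=seed,
                            protein_level=p, rem_reduction_light=0.4)
            hyp = simulate_hypnogram(cfg)
            return sleep.time_budget(hyp, cfg.start_time).minutes("REM", "light")

        wt = [light_rem(1.0, s) for s in range(20)]
        mut = [light_rem(0.0, 1000 + s) for s in range(20)]
        assert np.mean(mut) < np.mean(wt)

    def test_invalid_dwell_means_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(state_dwell_means={"WAKE": (0.0, 100.0),
                                         "NREM": (300.0, 180.0),
                                         "REM": (90.0, 70.0)})


class TestSignals:
    def test_wake_spectral_shape_matches_target(self):
        """Seed-averaged wake PSD follows the configured 1/f^chi shape
        (oracle: the analytic target spectrum, compared in log space)."""
        dwell = {"WAKE": (1e9, 1e9), "NREM": (300.0, 300.0), "REM": (90.0, 90.0)}
        psds = []
        for seed in range(30):
            cfg = SimConfig(sampling_rate=FS, duration_h=60 / 3600, seed=seed,
                            state_dwell_means=dwell, line_noise_amp=0.0,
                            artifact_rate=0.0, protein_level=1.0)
            hyp = simulate_hypnogram(cfg)
            assert set(hyp.labels) == {"WAKE"}
            rec, _ = synthesize_signals(hyp, cfg)
            res = spectral.welch_psd(rec.signals[0], FS, channel_labels=["a"])
            psds.append(res.psd[0])
        freqs = res.freqs
        mean_psd = np.mean(psds, axis=0)
        from psgpheno.simulate import _state_spectrum
        target = _state_spectrum(freqs, "WAKE", cfg)
        band = (freqs >= 2) & (freqs <= 100)
        ratio = mean_psd[band] / target[band]
        ratio /= ratio.mean()
        assert np.max(np.abs(np.log(ratio))) < 0.25  # within ~25% everywhere

    def test_mutant_band_effect_direction(self, wt_recording, mutant_recording):
        """Mutant has strictly higher 8-25 Hz and lower 50-100 Hz relative power."""
        def rel(rec):
            res = spectral.welch_psd(rec.signals[:3], FS,
                                     channel_labels=rec.channel_labels[:3])
            tab = spectral.band_powers(res)
            low = tab.relative[["alpha", "low_beta", "high_beta"]].sum(axis=1)
            return low.mean(), tab.relative["high_gamma"].mean()

        wt_low, wt_high = rel(wt_recording[0])
        mu_low, mu_high = rel(mutant_recording[0])
        assert mu_low > wt_low
        assert mu_high < wt_high

    def test_null_effect_sizes_indistinguishable(self):
        """With zero effect sizes, WT and 'mutant' band powers match."""
        from scipy import stats
        ratios = {1.0: [], 0.0: []}
        for p in ratios:
            for seed in range(10):
                cfg = SimConfig(sampling_rate=FS, duration_h=0.1,
                                seed=2000 + seed, protein_level=p,
                                band_effect_low=0.0, band_effect_high=0.0,
                                rem_reduction_light=0.0, artifact_rate=0.0)
                hyp = simulate_hypnogram(cfg)
                rec, _ = synthesize_signals(hyp, cfg)
                res = spectral.welch_psd(rec.signals[0], FS, channel_labels=["a"])
                ratios[p].append(float(spectral.band_powers(res).ratio_low_high.iloc[0]))
        _, pval = stats.ttest_ind(ratios[1.0], ratios[0.0])
        assert pval > 0.05

    def test_emg_rms_ordering(self, wt_recording):
        """EMG RMS obeys wake > NREM > REM within a recording."""
        rec, truth = wt_recording
        hyp = truth.state_sequence
        fs = rec.sampling_rate
        spe = int(hyp.epoch_s * fs)
        emg = rec.signals[-1]
        labels = np.asarray(hyp.labels, dtype=object)
        rms = {}
        for state in set(labels):
            idx = np.flatnonzero(labels == state)
            samples = np.concatenate([emg[k * spe:(k + 1) * spe] for k in idx])
            rms[state] = np.sqrt(np.mean(samples**2))
        if "NREM" in rms:
            assert rms["WAKE"] > rms["NREM"]
        if "REM" in rms and "NREM" in rms:
            assert rms["NREM"] > rms["REM"]

    def test_protein_level_shrinks_effects_monotonically(self):
        """Seed-averaged low-band excess decreases as protein level rises."""
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for p in grid:
            vals = []
            for seed in range(6):
                cfg = SimConfig(sampling_rate=FS, duration_h=0.1,
                                seed=3000 + seed, protein_level=p,
                                artifact_rate=0.0)
                hyp = simulate_hypnogram(cfg)
                rec, _ = synthesize_signals(hyp, cfg)
                res = spectral.welch_psd(rec.signals[0], FS, channel_labels=["a"])
                tab = spectral.band_powers(res)
                vals.append(float(
                    tab.relative[["alpha", "low_beta", "high_beta"]].sum(axis=1).iloc[0]
                ))
            means.append(np.mean(vals))
        assert all(means[i] > means[i + 1] for i in range(len(means) - 1))


class TestPolyspikeInjection:
    def test_zero_rate_zero_episodes(self, wt_recording, wt_config):
        rec, _ = wt_recording
        _, truth = inject_polyspikes(rec, 0.0, wt_config)
        assert truth.spike_episode_times == []

    def test_onset_counts_poisson(self, rng):
        """Episode counts over 50 seeds match Poisson(60) (oracle: the
        Poisson mean/variance at rate 10/h over 6 h)."""
        counts = [
            len(sample_episode_onsets(10.0, 6 * 3600.0, np.random.default_rng(s)))
            for s in range(50)
        ]
        se = np.sqrt(60.0 / 50)
        assert abs(np.mean(counts) - 60.0) <= 3 * se

    def test_each_episode_has_three_or_more_transients(self, wt_recording, wt_config):
        rec, _ = wt_recording
        _, truth = inject_polyspikes(rec, 20.0, wt_config)
        assert len(truth.spike_episode_counts) > 0
        assert all(n >= 3 for n in truth.spike_episode_counts)

    def test_negative_rate_rejected(self, wt_recording, wt_config, rng):
        rec, _ = wt_recording
        with pytest.raises(ConfigError):
            inject_polyspikes(rec, -1.0, wt_config, rng)

    def test_injection_does_not_mutate_input(self, wt_recording, wt_config):
        rec, _ = wt_recording
        before = rec.signals.copy()
        inject_polyspikes(rec, 20.0, wt_config)
        np.testing.assert_array_equal(rec.signals, before)


class TestCohort:
    def test_file_counts_and_manifest(self, tmp_path):
        cfg = SimConfig(sampling_rate=250, duration_h=60 / 3600, seed=9)
        specs = [("WT", "control", 3, 1.0), ("mutant", "control", 3, 0.0),
                 ("mutant", "aso", 3, 0.6), ("mutant", "aso2", 3, 0.3)]
        manifest = simulate_cohort(specs, cfg, tmp_path / "cohort")
        assert len(manifest) == 12
        assert len(list((tmp_path / "cohort").glob("*.edf"))) == 12
        assert len(list((tmp_path / "cohort").glob("*_hypnogram.csv"))) == 12
        assert (tmp_path / "cohort" / "manifest.csv").exists()
        expected = [1.0] * 3 + [0.0] * 3 + [0.6] * 3 + [0.3] * 3
        assert list(manifest["protein_level"]) == expected

    def test_rerun_byte_identical_sidecars(self, tmp_path):
        cfg = SimConfig(sampling_rate=250, duration_h=30 / 3600, seed=11)
        specs = [("WT", "control", 1, 1.0)]
        simulate_cohort(specs, cfg, tmp_path / "a")
        simulate_cohort(specs, cfg, tmp_path / "b")
        for name in ("WT_control_000_hypnogram.csv", "WT_control_000_events.csv",
                     "WT_control_000_covariates.json", "WT_control_000.edf"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_invalid_group_size_rejected(self, tmp_path):
        cfg = SimConfig(sampling_rate=250, duration_h=30 / 3600, seed=1)
        with pytest.raises(ConfigError):
            simulate_cohort([("WT", "control", 0, 1.0)], cfg, tmp_path / "x")


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"duration_h": 0},
        {"rem_reduction_light": 1.0},
        {"protein_level": 1.5},
        {"light_hours": 24.0},
        {"spike_rate": -1.0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimConfig(**kw)
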