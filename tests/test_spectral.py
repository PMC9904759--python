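"""Welch PSD, notch-band interpolation, band powers, the low/high ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psgpheno.preprocess import ArtifactMask
from psgpheno.spectral import (
    BANDS,
    PSDResult,
    SpectralError,
    band_powers,
    interpolate_notch_band,
    power_ratio,
    relative_psd,
    welch_psd,
)

FS = 5000.0


def _flat_psd(value=1.0, df=0.5, fmax=150.0, n_ch=1):
    freqs = np.arange(0, fmax + df, df)
    return PSDResult(freqs=freqs, psd=np.full((n_ch, len(freqs)), value),
                     n_segments=1, channel_labels=[f"ch{i}" for i in range(n_ch)])


class TestWelch:
    def test_grid_spacing_is_half_hz(self):
        res = welch_psd(np.random.default_rng(0).normal(size=int(10 * FS)), FS)
        assert res.df == pytest.approx(0.5)
        assert np.allclose(np.diff(res.freqs), 0.5)

    def test_zero_signal_zero_psd(self):
        res = welch_psd(np.zeros(int(10 * FS)), FS)
        np.testing.assert_allclose(res.psd, 0.0)

    def test_sinusoid_parseval(self):
        """Unit 10 Hz sinusoid: integrated 1-100 Hz power = 1/2 within 2%."""
        t = np.arange(0, 60, 1 / FS)
        res = welch_psd(np.sin(2 * np.pi * 10 * t), FS)
        band = (res.freqs >= 1) & (res.freqs <= 100)
        power = np.trapezoid(res.psd[0][band], res.freqs[band])
        assert power == pytest.approx(0.5, rel=0.02)

    def test_white_noise_variance(self, rng):
        """White noise: integral over 0-Nyquist = sigma^2 within 5%."""
        sigma = 3.0
        x = rng.normal(0, sigma, size=int(60 * FS))
        res = welch_psd(x, FS)
        total = np.trapezoid(res.psd[0], res.freqs)
        assert total == pytest.approx(sigma**2, rel=0.05)

    def test_matches_scipy_welch(self, rng):
        """Independent oracle: scipy's Welch with identical parameters."""
        from scipy import signal as sps
        x = rng.normal(size=int(30 * 500))
        res = welch_psd(x, 500.0)
        f, p = sps.welch(x, fs=500.0, window=np.hanning(1000), nperseg=1000,
                         noverlap=500, detrend="constant")
        np.testing.assert_allclose(res.freqs, f)
        np.testing.assert_allclose(res.psd[0], p, rtol=1e-10, atol=1e-18)

    def test_masked_windows_excluded_from_segments(self, rng):
        """A segment overlapping an artifact window never enters the average."""
        fs = 500.0
        n = int(20 * fs)
        x = rng.normal(size=n)
        x[int(9 * fs):int(10 * fs)] += 1000.0  # huge artifact second
        per_channel = np.zeros((1, 20), dtype=bool)
        per_channel[0, 9] = True
        mask = ArtifactMask(per_channel=per_channel, window_s=1.0,
                            z_thresh=8.0, channel_labels=["a"])
        res_masked = welch_psd(x, fs, artifact_mask=mask)
        res_raw = welch_psd(x, fs)
        assert res_masked.psd[0].max() < res_raw.psd[0].max() / 10
        assert res_masked.n_segments < res_raw.n_segments

    def test_no_clean_segment_rejected(self):
        per_channel = np.ones((1, 4), dtype=bool)
        mask = ArtifactMask(per_channel=per_channel, window_s=1.0,
                            z_thresh=8.0, channel_labels=["a"])
        with pytest.raises(SpectralError):
            welch_psd(np.zeros(int(4 * 500)), 500.0, artifact_mask=mask)


class TestInterpolation:
    def test_straight_line_is_fixed_point(self):
        freqs = np.arange(0, 150.5, 0.5)
        psd = (2.0 + 0.03 * freqs)[None, :]
        res = PSDResult(freqs=freqs, psd=psd, n_segments=1, channel_labels=["a"])
        out = interpolate_notch_band(res)
        np.testing.assert_allclose(out.psd, psd, rtol=1e-9)

    def test_spike_on_flat_background_removed(self):
        res = _flat_psd(value=4.0)
        i60 = int(np.flatnonzero(res.freqs == 60.0)[0])
        res.psd[0, i60] = 500.0
        out = interpolate_notch_band(res)
        band = (out.freqs >= 58) & (out.freqs <= 62)
        np.testing.assert_allclose(out.psd[0][band], 4.0, atol=1e-9)

    def test_values_outside_band_untouched(self):
        res = _flat_psd(value=1.0)
        res.psd[0] += np.random.default_rng(3).uniform(0, 1, res.psd.shape[1])
        out = interpolate_notch_band(res)
        outside = (out.freqs < 58) | (out.freqs > 62)
        np.testing.assert_array_equal(out.psd[0][outside], res.psd[0][outside])
        i575 = np.flatnonzero(res.freqs == 57.5)[0]
        i625 = np.flatnonzero(res.freqs == 62.5)[0]
        assert out.psd[0, i575] == res.psd[0, i575]
        assert out.psd[0, i625] == res.psd[0, i625]

    def test_flank_means_method_on_flat_background(self):
        res = _flat_psd(value=2.0)
        i60 = int(np.flatnonzero(res.freqs == 60.0)[0])
        res.psd[0, i60] = 100.0
        out = interpolate_notch_band(res, method="flank_means")
        band = (out.freqs >= 58) & (out.freqs <= 62)
        np.testing.assert_allclose(out.psd[0][band], 2.0, atol=1e-9)

    def test_insufficient_flanking_points_rejected(self):
        freqs = np.arange(55, 65.5, 0.5)
        res = PSDResult(freqs=freqs, psd=np.ones((1, len(freqs))),
                        n_segments=1, channel_labels=["a"])
        with pytest.raises(SpectralError):
            interpolate_notch_band(res)

    def test_interpolated_range_recorded(self):
        out = interpolate_notch_band(_flat_psd())
        assert out.interpolated_range == (58.0, 62.0)


class TestBandPowers:
    def test_flat_psd_analytic_band_powers(self):
        """Flat PSD=c: delta power 3c, high-gamma 50c, relative gamma2 50/99."""
        c = 2.5
        tab = band_powers(_flat_psd(value=c))
        assert tab.absolute.loc["ch0", "delta"] == pytest.approx(3 * c)
        assert tab.absolute.loc["ch0", "high_gamma"] == pytest.approx(50 * c)
        assert tab.relative.loc["ch0", "high_gamma"] == pytest.approx(50 / 99)

    def test_pure_2hz_sinusoid_delta_dominant(self):
        t = np.arange(0, 60, 1 / FS)
        res = welch_psd(np.sin(2 * np.pi * 2 * t), FS)
        tab = band_powers(res)
        assert tab.relative.loc["ch0", "delta"] >= 0.95

    def test_zero_psd_rejected(self):
        res = _flat_psd(value=0.0)
        with pytest.raises(SpectralError, match="relative powers undefined"):
            band_powers(res)

    def test_off_grid_band_edge_rejected(self):
        res = _flat_psd()
        with pytest.raises(SpectralError, match="off the"):
            band_powers(res, bands={"odd": (1.25, 4.0)})

    def test_band_partition_conservation(self, rng):
        """Seven absolute band powers sum exactly to the 1-100 Hz total."""
        psd = rng.uniform(0.1, 5.0, size=(3, 301))
        res = PSDResult(freqs=np.arange(0, 150.5, 0.5), psd=psd,
                        n_segments=1, channel_labels=["a", "b", "c"])
        tab = band_powers(res)
        np.testing.assert_allclose(tab.absolute.sum(axis=1), tab.total_power,
                                   rtol=1e-9)


class TestRatio:
    def test_flat_psd_ratio_034(self):
        tab = band_powers(_flat_psd(value=7.3))
        assert float(tab.ratio_low_high.iloc[0]) == pytest.approx(17 / 50)
        assert 17 / 50 == 0.34

    def test_absolute_equals_relative_ratio_machine_precision(self, rng):
        """The paper-level invariance: the ratio does not depend on whether
        PSD or relative PSD is used."""
        psd = rng.uniform(0.01, 10.0, size=(2, 301))
        res = PSDResult(freqs=np.arange(0, 150.5, 0.5), psd=psd,
                        n_segments=1, channel_labels=["a", "b"])
        tab = band_powers(res)
        r_abs = power_ratio(tab, use_relative=False)
        r_rel = power_ratio(tab, use_relative=True)
        np.testing.assert_allclose(r_abs, r_rel, rtol=1e-12)
        tab_rel = band_powers(relative_psd(res))
        np.testing.assert_allclose(tab.ratio_low_high, tab_rel.ratio_low_high,
                                   rtol=1e-9)

    def test_power_concentrated_in_high_gamma_ratio_near_zero(self):
        freqs = np.arange(0, 150.5, 0.5)
        psd = np.full((1, len(freqs)), 1e-9)
        psd[0, (freqs >= 50) & (freqs <= 100)] = 10.0
        res = PSDResult(freqs=freqs, psd=psd, n_segments=1, channel_labels=["a"])
        assert float(band_powers(res).ratio_low_high.iloc[0]) < 1e-6

    def test_zero_gamma_power_is_error_not_infinity(self):
        freqs = np.arange(0, 150.5, 0.5)
        psd = np.zeros((1, len(freqs)))
        psd[0, (freqs >= 1) & (freqs <= 40)] = 1.0
        res = PSDResult(freqs=freqs, psd=psd, n_segments=1, channel_labels=["a"])
        with pytest.raises(SpectralError, match="ratio undefined"):
            band_powers(res)

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_ratio_invariant_to_positive_rescaling(self, scale):
        rng = np.random.default_rng(99)
        psd = rng.uniform(0.01, 10.0, size=(1, 301))
        freqs = np.arange(0, 150.5, 0.5)
        res1 = PSDResult(freqs=freqs, psd=psd, n_segments=1, channel_labels=["a"])
        res2 = PSDResult(freqs=freqs, psd=psd * scale, n_segments=1,
                         channel_labels=["a"])
        r1 = band_powers(res1).ratio_low_high.iloc[0]
        r2 = band_powers(res2).ratio_low_high.iloc[0]
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestRelativePSD:
    def test_integrates_to_one(self, rng):
        psd = rng.uniform(0.1, 5.0, size=(2, 301))
        res = PSDResult(freqs=np.arange(0, 150.5, 0.5), psd=psd,
                        n_segments=1, channel_labels=["a", "b"])
        out = relative_psd(res)
        band = (out.freqs >= 1) & (out.freqs <= 100)
        integ = np.trapezoid(out.psd[:, band], out.freqs[band], axis=1)
        np.testing.assert_allclose(integ, 1.0, rtol=1e-9)

    def test_scale_invariant(self, rng):
        psd = rng.uniform(0.1, 5.0, size=(1, 301))
        freqs = np.arange(0, 150.5, 0.5)
        res = PSDResult(freqs=freqs, psd=psd, n_segments=1, channel_labels=["a"])
        res7 = PSDResult(freqs=freqs, psd=7 * psd, n_segments=1,
                         channel_labels=["a"])
        np.testing.assert_allclose(relative_psd(res).psd, relative_psd(res7).psd,
                                   rtol=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(SpectralError):
            relative_psd(_flat_psd(value=0.0))
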