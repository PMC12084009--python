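"""Welch PSD and masked log-log aperiodic fitting."""

import numpy as np
import pytest

from neuroei.preprocess import epoch
from neuroei.spectral import (average_occipital, fit_aperiodic,
                              normalize_spectrum, welch_psd)
from neuroei.types import AperiodicFit, PowerSpectrum, TimeSeriesRecording


def _power_law_spectrum(chi=2.0, scale=1.0, fs=1000.0, window=1000,
                        labels=("O1",), bump=None):
    freqs = np.arange(0.0, fs / 2 + 1e-9, fs / window)
    power = np.zeros((len(labels), freqs.size))
    with np.errstate(divide="ignore"):
        p = scale * np.where(freqs > 0, freqs, np.nan) ** (-chi)
    p[0] = p[1]
    for i in range(len(labels)):
        power[i] = p
        if bump is not None:
            lo, hi, height = bump
            band = (freqs >= lo) & (freqs <= hi)
            power[i, band] += height
    return PowerSpectrum(frequencies=freqs, power=power,
                         channel_labels=list(labels), n_epochs_used=1)


class TestWelch:
    def test_frequency_grid_resolution(self, clean_recording):
        ps = welch_psd(epoch(clean_recording, 1.0), window=1000)
        np.testing.assert_allclose(ps.frequencies,
                                   np.arange(0.0, 501.0, 1.0))

    def test_sine_band_power_matches_parseval(self):
        """A unit 5 Hz sine carries amplitude²/2 = 0.5 μV² of band power."""
        fs, dur = 1000.0, 30.0
        t = np.arange(int(fs * dur)) / fs
        ts = TimeSeriesRecording(np.sin(2 * np.pi * 5.0 * t)[None, :], fs,
                                 ["O1"])
        ps = welch_psd(epoch(ts, 1.0), window=1000)
        band = (ps.frequencies >= 3) & (ps.frequencies <= 7)
        bp = np.trapezoid(ps.power[0, band], ps.frequencies[band])
        assert bp == pytest.approx(0.5, rel=0.03)

    def test_white_noise_density_level(self, rng):
        fs, sigma = 1000.0, 2.0
        x = sigma * rng.standard_normal(int(fs * 60))
        ts = TimeSeriesRecording(x[None, :], fs, ["O1"])
        ps = welch_psd(epoch(ts, 1.0), window=1000)
        band = (ps.frequencies >= 1) & (ps.frequencies <= 45)
        assert ps.power[0, band].mean() == pytest.approx(
            sigma ** 2 / (fs / 2), rel=0.05)

    def test_all_epochs_rejected_is_an_error(self, clean_recording):
        e = epoch(clean_recording, 1.0)
        e.rejected[:] = True
        with pytest.raises(ValueError):
            welch_psd(e)

    def test_window_longer_than_epoch_rejected(self, clean_recording):
        with pytest.raises(ValueError):
            welch_psd(epoch(clean_recording, 1.0), window=2000)


class TestNormalization:
    def test_mean_density_over_fit_range_is_one(self, clean_recording):
        ps = welch_psd(epoch(clean_recording, 1.0))
        norm = normalize_spectrum(ps)
        band = (norm.frequencies >= 1) & (norm.frequencies <= 20)
        assert norm.power[:, band].mean(axis=1) == pytest.approx(1.0,
                                                                 abs=1e-12)

    def test_scale_invariance(self, clean_recording):
        ps = welch_psd(epoch(clean_recording, 1.0))
        scaled = PowerSpectrum(frequencies=ps.frequencies,
                               power=10.0 * ps.power,
                               channel_labels=ps.channel_labels,
                               n_epochs_used=ps.n_epochs_used)
        a, b = normalize_spectrum(ps), normalize_spectrum(scaled)
        np.testing.assert_allclose(a.power, b.power, rtol=1e-12)
        np.testing.assert_allclose(b.normalization, 10.0 * a.normalization,
                                   rtol=1e-12)

    def test_slope_identical_before_and_after_normalization(self):
        ps = _power_law_spectrum(chi=1.7)
        raw = fit_aperiodic(ps)[0]
        normed = fit_aperiodic(normalize_spectrum(ps))[0]
        assert normed.slope == pytest.approx(raw.slope, abs=1e-12)
        # and the stored constant makes the intercept refer to the raw scale
        assert normed.intercept == pytest.approx(raw.intercept, abs=1e-9)

    def test_zero_spectrum_rejected(self):
        ps = _power_law_spectrum()
        ps.power[:] = 0.0
        with pytest.raises(ValueError):
            normalize_spectrum(ps)


class TestAperiodicFit:
    def test_exact_power_law_recovered_exactly(self):
        fit = fit_aperiodic(_power_law_spectrum(chi=2.0, scale=1.0))[0]
        assert fit.slope == pytest.approx(-2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.fit_error < 1e-10

    def test_flat_spectrum_zero_slope(self):
        ps = _power_law_spectrum(chi=0.0, scale=7.0)
        fit = fit_aperiodic(ps)[0]
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.intercept == pytest.approx(np.log10(7.0), abs=1e-10)

    def test_alpha_band_bump_fully_masked(self):
        """A bump confined to 8–14 Hz leaves the masked fit untouched."""
        clean = fit_aperiodic(_power_law_spectrum(chi=1.5))[0]
        bumped = fit_aperiodic(_power_law_spectrum(chi=1.5,
                                                   bump=(8.0, 14.0, 3.0)))[0]
        assert bumped.slope == pytest.approx(clean.slope, abs=1e-9)
        assert bumped.intercept == pytest.approx(clean.intercept, abs=1e-9)

    def test_masked_bins_exclude_band_edges(self):
        ps = _power_law_spectrum(fs=60.0, window=60)
        fit = fit_aperiodic(ps)[0]
        # integer-Hz grid: {1..7} ∪ {15..20} = 13 bins
        assert fit.n_bins == 13

    def test_matches_normal_equations_oracle(self, rng):
        """Brute-force normal-equations solution agrees to 1e-9."""
        for _ in range(5):
            chi = rng.uniform(0.3, 2.5)
            noise = rng.normal(0, 0.05, 501)
            ps = _power_law_spectrum(chi=chi)
            ps.power[0] *= 10 ** noise
            fit = fit_aperiodic(ps)[0]
            f = ps.frequencies
            m = ((f >= 1) & (f <= 20)) & ~((f >= 8) & (f <= 14))
            X = np.column_stack([np.ones(m.sum()), np.log10(f[m])])
            y = np.log10(ps.power[0, m])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
            assert fit.slope == pytest.approx(beta[1], abs=1e-9)

    def test_nonpositive_power_rejected(self):
        ps = _power_law_spectrum()
        ps.power[0, 5] = 0.0
        with pytest.raises(ValueError):
            fit_aperiodic(ps)


class TestOccipitalAveraging:
    def _fit(self, slope, intercept, channel):
        return AperiodicFit(slope=slope, intercept=intercept, fit_error=0.0,
                            r_squared=1.0, channel=channel)

    def test_identical_fits_idempotent(self):
        fits = [self._fit(-1.0, 0.5, "O1"), self._fit(-1.0, 0.5, "O2")]
        assert average_occipital(fits) == (-1.0, 0.5)

    def test_arithmetic_mean(self):
        fits = [self._fit(-1.0, 0.2, "O1"), self._fit(-1.4, 0.6, "O2")]
        slope, intercept = average_occipital(fits)
        assert slope == pytest.approx(-1.2)
        assert intercept == pytest.approx(0.4)

    def test_missing_electrode_named_in_error(self):
        with pytest.raises(KeyError, match="O2"):
            average_occipital([self._fit(-1.0, 0.0, "O1")])

    def test_fit_then_average_differs_from_fit_of_average(self):
        """Parameter averaging is pinned: it differs in general from fitting
        the channel-averaged spectrum (log of a mean ≠ mean of logs)."""
        ps = _power_law_spectrum(chi=1.0, labels=("O1", "O2"))
        ps.power[1] = 100.0 * _power_law_spectrum(chi=2.0).power[0]
        fits = fit_aperiodic(ps)
        slope_avg, _ = average_occipital(fits)
        mean_ps = PowerSpectrum(frequencies=ps.frequencies,
                                power=ps.power.mean(axis=0, keepdims=True),
                                channel_labels=["O1"], n_epochs_used=1)
        slope_of_mean = fit_aperiodic(mean_ps)[0].slope
        assert slope_avg == pytest.approx(-1.5, abs=1e-9)
        assert abs(slope_avg - slope_of_mean) > 0.05
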