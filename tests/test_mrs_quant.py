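"""Edited-MRS quantification: difference spectrum, fits, normalization,
quality metrics."""

import numpy as np
import pytest
from lmfit.lineshapes import gaussian

from neuroei.mrs import (TissueConstants, combine_edited, cr_normalize,
                         discrimination_experiment, estimate_noise,
                         fit_diff_peaks, fit_off_peaks, fit_water,
                         glx_gaba_ratio, quality_metrics,
                         quantify_acquisition, water_normalize)
from neuroei.synthetic_mrs import (MRSSimSpec,
                                   generate_mega_press_acquisition)
from neuroei.types import MRSAcquisition, TissueFractions


class TestCombineEdited:
    def test_on_equals_off_gives_zero(self, noise_free_acquisition):
        acq = noise_free_acquisition
        same = MRSAcquisition(ppm=acq.ppm, on=acq.off, off=acq.off,
                              water=acq.water)
        assert np.abs(combine_edited(same)).max() == 0.0

    def test_mismatched_axes_rejected(self, noise_free_acquisition):
        acq = noise_free_acquisition
        with pytest.raises(ValueError):
            MRSAcquisition(ppm=acq.ppm[:-1], on=acq.on, off=acq.off,
                           water=acq.water)

    def test_alignment_recovers_rigid_shift(self, noise_free_acquisition):
        acq = noise_free_acquisition
        shifted = MRSAcquisition(ppm=acq.ppm, on=np.roll(acq.on, 3),
                                 off=acq.off, water=acq.water)
        aligned = combine_edited(shifted, align=True)
        plain = combine_edited(acq)
        # interior points recover the unshifted difference
        np.testing.assert_allclose(aligned[10:-10], plain[10:-10],
                                   atol=1e-10)


class TestPeakFits:
    def test_noise_free_recovery_is_exact(self, noise_free_acquisition):
        acq = noise_free_acquisition
        truth = acq.metadata["truth"]
        diff_fits = fit_diff_peaks(combine_edited(acq), acq.ppm)
        off_fits = fit_off_peaks(acq.off, acq.ppm)
        wfit = fit_water(acq.water, acq.ppm)
        assert diff_fits["GABA+"].area == pytest.approx(
            truth["gaba_plus_area"], rel=1e-6)
        assert diff_fits["Glx"].area == pytest.approx(truth["glx_area"],
                                                      rel=1e-6)
        assert off_fits["NAA"].area == pytest.approx(truth["naa_area"],
                                                     rel=1e-6)
        assert off_fits["Cr"].area == pytest.approx(truth["cr_area"],
                                                    rel=1e-6)
        assert wfit.area == pytest.approx(truth["water_area"], rel=1e-6)

    def test_null_gaba_area_consistent_with_zero(self):
        spec = MRSSimSpec(concentrations={"GABA": 0.0, "Glx": 10.0,
                                          "NAA": 12.0, "Cr": 8.0},
                          mm_contamination=0.0, seed=4)
        acq = generate_mega_press_acquisition(spec)
        fit = fit_diff_peaks(combine_edited(acq), acq.ppm)["GABA+"]
        assert abs(fit.area) < 3.0 * fit.area_stderr

    def test_doubling_naa_doubles_area(self):
        areas = []
        for naa in (6.0, 12.0):
            spec = MRSSimSpec(concentrations={"GABA": 2.0, "Glx": 10.0,
                                              "NAA": naa, "Cr": 8.0},
                              noise_sd=0.0, seed=1)
            acq = generate_mega_press_acquisition(spec)
            areas.append(fit_off_peaks(acq.off, acq.ppm)["NAA"].area)
        assert areas[1] / areas[0] == pytest.approx(2.0, rel=1e-6)

    def test_repeatability_within_fit_uncertainty(self):
        """Across seeds the fitted area scatters on the scale the parameter
        covariance predicts (same spec, different noise)."""
        areas, stderrs = [], []
        for seed in range(8):
            acq = generate_mega_press_acquisition(MRSSimSpec(seed=seed))
            fit = fit_diff_peaks(combine_edited(acq), acq.ppm)["GABA+"]
            areas.append(fit.area)
            stderrs.append(fit.area_stderr)
        scatter = np.std(areas, ddof=1)
        predicted = np.mean(stderrs)
        assert 0.3 * predicted < scatter < 3.0 * predicted


class TestNormalization:
    def test_degenerate_correction_reduces_to_water_scaling(self):
        tissue = TissueFractions(f_gm=0.5, f_wm=0.5, f_csf=0.0)
        constants = TissueConstants(k_gm=0.7, k_wm=0.7, k_csf=0.7,
                                    water_conc=55.5, alpha=1.0)
        c = water_normalize(2.0, 100.0, tissue, constants)
        assert c == pytest.approx(2.0 / 100.0 * 55.5 * 0.7, rel=1e-12)

    def test_concentration_increases_with_csf_fraction(self):
        prev = -np.inf
        for f_csf in (0.0, 0.1, 0.2, 0.3):
            par = (1.0 - f_csf) / 2.0
            tissue = TissueFractions(f_gm=par, f_wm=par, f_csf=f_csf)
            c = water_normalize(2.0, 100.0, tissue)
            assert c > prev
            prev = c

    def test_pure_csf_voxel_rejected(self):
        with pytest.raises(ValueError):
            water_normalize(2.0, 100.0,
                            TissueFractions(f_gm=0.0, f_wm=0.0, f_csf=1.0))

    def test_tissue_fraction_validation(self):
        with pytest.raises(ValueError):
            TissueFractions(f_gm=0.5, f_wm=0.6, f_csf=0.1)  # sum > 1

    def test_cr_ratio_unity_and_gain_invariance(self):
        assert cr_normalize(3.0, 3.0) == 1.0
        assert cr_normalize(2.0, 8.0) == cr_normalize(20.0, 80.0)

    def test_glx_gaba_ratio_properties(self):
        assert glx_gaba_ratio(2.0, 2.0) == 1.0
        assert glx_gaba_ratio(6.0, 2.0) == glx_gaba_ratio(60.0, 20.0)
        with pytest.raises(ValueError):
            glx_gaba_ratio(1.0, 0.0)

    def test_end_to_end_concentration_ratio(self):
        """GABA 2.0 vs 3.0 mM → water-normalized estimates in ratio 1.5."""
        out = []
        for conc in (2.0, 3.0):
            spec = MRSSimSpec(concentrations={"GABA": conc, "Glx": 10.0,
                                              "NAA": 12.0, "Cr": 8.0},
                              noise_sd=0.0, seed=1)
            q = quantify_acquisition(generate_mega_press_acquisition(spec))
            out.append(q.gaba_plus)
        assert out[1] / out[0] == pytest.approx(1.5, rel=0.01)


class TestQualityMetrics:
    def test_gaussian_fwhm_analytic_identity(self):
        """FWHM(Hz) = 2√(2 ln 2)·σ·field_mhz for a Gaussian peak."""
        ppm = np.linspace(0.0, 5.0, 4096)
        sigma, field = 0.05, 127.7
        y = gaussian(ppm, amplitude=2.0, center=3.0, sigma=sigma)
        fit = fit_diff_peaks(y, ppm)["GABA+"]
        q = quality_metrics(fit, y, ppm, field)
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma * field
        assert q.fwhm_hz == pytest.approx(expected, rel=1e-6)

    def test_noise_free_fit_error_vanishes(self):
        ppm = np.linspace(0.0, 5.0, 4096)
        y = gaussian(ppm, amplitude=2.0, center=3.0, sigma=0.05)
        fit = fit_diff_peaks(y, ppm)["GABA+"]
        q = quality_metrics(fit, y, ppm, 127.7)
        assert q.fit_error_pct < 1e-8

    def test_doubling_noise_halves_snr(self):
        snrs = []
        for noise in (5.0, 10.0):
            vals = []
            for seed in range(6):
                acq = generate_mega_press_acquisition(
                    MRSSimSpec(noise_sd=noise, seed=seed))
                q = quantify_acquisition(acq)
                vals.append(q.quality["GABA+"].snr)
            snrs.append(np.mean(vals))
        assert snrs[0] / snrs[1] == pytest.approx(2.0, rel=0.25)

    def test_empty_noise_window_rejected(self, noise_free_acquisition):
        acq = noise_free_acquisition
        with pytest.raises(ValueError):
            estimate_noise(acq.off, acq.ppm, window=(9.5, 10.5))


class TestDiscrimination:
    def test_noise_free_ordering_is_perfect(self):
        out = discrimination_experiment(base_conc=2.0, delta=0.02,
                                        snr_level=None, n_sim=3, seed=0)
        assert out["fraction_ordered"] == 1.0

    def test_zero_delta_is_chance(self):
        out = discrimination_experiment(base_conc=2.0, delta=0.0,
                                        snr_level=40.0, n_sim=30, seed=1)
        assert 0.2 < out["fraction_ordered"] < 0.8

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            discrimination_experiment(delta=-0.01)


def test_flags_raised_for_nan_free_quantification(noisy_acquisition):
    q = quantify_acquisition(noisy_acquisition)
    assert np.isfinite(q.gaba_plus) and np.isfinite(q.glx)
    assert np.isfinite(q.glx_gaba_ratio)
    assert q.quality["GABA+"].snr > 5.0
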