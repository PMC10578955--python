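import numpy as np
import pytest

from qustex.spectral import (
    AnalysisBand,
    AttenuationModel,
    NormalizedSpectrum,
    anderson_form_factor,
    compute_window_spectrum,
    fit_form_factor,
    fit_spectral_line,
    gaussian_form_factor,
    normalize_spectrum,
    unnormalized_fluid_sphere_cross_section,
)
from qustex.spectral import (
    _fluid_sphere_backscatter_amplitude,
    _rayleigh_backscatter_amplitude,
)

FS = 40e6


def _flat_spectrum(value_db=0.0, depth=1.0):
    f = np.linspace(0.0, 20.0, 201)
    return NormalizedSpectrum(frequencies=f, values=np.full_like(f, value_db),
                              window_depth=depth)


class TestWindowSpectrum:
    def test_tone_peak_at_5mhz(self):
        t = np.arange(512) / FS
        window = np.sin(2 * np.pi * 5e6 * t)[:, None] * np.ones((1, 4))
        freqs, power = compute_window_spectrum(window, FS)
        assert freqs[np.argmax(power)] == pytest.approx(5.0, abs=0.1)

    def test_amplitude_scaling_quadratic(self, rng):
        window = rng.normal(size=(128, 8))
        _, p1 = compute_window_spectrum(window, FS)
        _, p2 = compute_window_spectrum(2.0 * window, FS)
        np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-12)

    def test_all_zero_window_flagged_not_raised(self):
        freqs, power = compute_window_spectrum(np.zeros((64, 4)), FS)
        assert (power == 0).all()

    def test_white_noise_flat_vs_periodogram_oracle(self, rng):
        # oracle: direct periodogram averaging over many independent lines
        n, sigma2 = 128, 2.0
        lines = rng.normal(0.0, np.sqrt(sigma2), size=(n, 10_000))
        freqs, power = compute_window_spectrum(lines, FS)
        taper = np.hamming(n)
        oracle = np.zeros(len(freqs))
        for chunk in np.array_split(lines, 50, axis=1):
            spec = np.fft.rfft(chunk * taper[:, None], n=128, axis=0)
            oracle += np.sum(np.abs(spec) ** 2, axis=1)
        oracle /= lines.shape[1]
        band = (freqs >= 3) & (freqs <= 8)
        assert np.mean(power[band]) == pytest.approx(np.mean(oracle[band]), rel=1e-12)
        # flat in expectation: in-band mean of the estimate ~ sigma^2 * sum(w^2)
        expected = sigma2 * np.sum(taper ** 2)
        assert np.mean(power[band]) == pytest.approx(expected, rel=0.1)

    def test_too_small_window_raises(self):
        with pytest.raises(ValueError):
            compute_window_spectrum(np.zeros((8, 4)), FS)
        with pytest.raises(ValueError):
            compute_window_spectrum(np.zeros((64, 1)), FS)


class TestNormalize:
    def test_identity(self):
        f = np.linspace(0, 20, 101)
        p = np.exp(-((f - 10) / 4) ** 2) + 0.1
        ns = normalize_spectrum((f, p), (f, p), AttenuationModel(), depth=2.0)
        np.testing.assert_allclose(ns.values, 0.0, atol=1e-12)

    def test_point_compensation_arithmetic(self):
        f = np.linspace(0, 20, 201)
        p = np.ones_like(f)
        atten = AttenuationModel(local_attenuation=0.5)
        ns = normalize_spectrum((f, p), (f, p), atten, depth=2.0)
        idx = np.argmin(np.abs(f - 5.0))
        assert ns.values[idx] == pytest.approx(4 * 0.5 * 2.0 * 5.0)  # 20 dB

    def test_zero_compensation_when_alpha_or_depth_zero(self):
        f = np.linspace(0, 20, 21)
        assert AttenuationModel(0.0).compensation_db(f, 3.0) == pytest.approx(0.0)
        assert np.allclose(AttenuationModel(0.7).compensation_db(f, 0.0), 0.0)

    def test_grid_mismatch_raises(self):
        f1 = np.linspace(0, 20, 101)
        f2 = np.linspace(0, 10, 101)
        with pytest.raises(ValueError):
            normalize_spectrum((f1, np.ones(101)), (f2, np.ones(101)),
                               AttenuationModel(), 1.0)

    def test_nonpositive_reference_in_band_raises(self):
        f = np.linspace(0, 20, 101)
        ref = np.ones(101)
        ref[30] = 0.0  # 6 MHz
        with pytest.raises(ValueError):
            normalize_spectrum((f, np.ones(101)), (f, ref), AttenuationModel(),
                               1.0, band=AnalysisBand())


class TestSpectralLine:
    def test_exact_line(self):
        f = np.linspace(0, 20, 401)
        ns = NormalizedSpectrum(f, 2.0 * f + 4.0, window_depth=1.0)
        fit = fit_spectral_line(ns, AnalysisBand(3, 8))
        assert fit.SS == pytest.approx(2.0, abs=1e-10)
        assert fit.SI == pytest.approx(4.0, abs=1e-10)
        assert fit.MBF == pytest.approx(15.0, abs=1e-10)

    def test_constant_spectrum(self):
        fit = fit_spectral_line(_flat_spectrum(-7.0), AnalysisBand())
        assert fit.SS == pytest.approx(0.0, abs=1e-12)
        assert fit.SI == pytest.approx(-7.0)
        assert fit.MBF == pytest.approx(-7.0)

    def test_mbf_identity_holds(self, rng):
        f = np.linspace(0, 20, 256)
        for _ in range(50):
            ns = NormalizedSpectrum(f, rng.normal(size=f.size), window_depth=1.0)
            band = AnalysisBand(3, 8)
            fit = fit_spectral_line(ns, band)
            assert fit.MBF == pytest.approx(fit.SI + fit.SS * band.f_center,
                                            rel=1e-12, abs=1e-12)

    def test_noisy_line_slope_recovery(self, rng):
        f = np.linspace(0, 20, 201)
        band = AnalysisBand()
        m = band.mask(f)
        slopes = []
        for _ in range(200):
            vals = 1.5 * f - 3.0 + rng.normal(0, 1.0, size=f.size)
            slopes.append(fit_spectral_line(NormalizedSpectrum(f, vals, 1.0), band).SS)
        # OLS sampling distribution: SE of slope = sigma / sqrt(Sxx)
        sxx = np.sum((f[m] - f[m].mean()) ** 2)
        se_mean = 1.0 / np.sqrt(sxx) / np.sqrt(200)
        assert np.mean(slopes) == pytest.approx(1.5, abs=2 * se_mean * 3)

    def test_too_few_bins_raises(self):
        f = np.array([1.0, 5.0, 12.0])
        with pytest.raises(ValueError):
            fit_spectral_line(NormalizedSpectrum(f, np.zeros(3), 1.0), AnalysisBand())


class TestFormFactors:
    def test_gaussian_rayleigh_limit(self):
        assert gaussian_form_factor(1e-9, 80.0) == pytest.approx(1.0)

    def test_gaussian_monotone_in_f_and_diameter(self):
        f = np.linspace(0.1, 15, 50)
        ff = gaussian_form_factor(f, 80.0)
        assert (np.diff(ff) < 0).all()
        d = np.linspace(10, 200, 50)
        vals = [gaussian_form_factor(5.0, di) for di in d]
        assert (np.diff(vals) < 0).all()

    def test_gaussian_closed_form_value(self):
        # independent arithmetic: k = 2*pi*f/c, a = d/2
        f, d, c = 5.0, 80.0, 1540.0
        k = 2 * np.pi * f * 1e6 / c
        a = 40e-6
        assert gaussian_form_factor(f, d, c) == pytest.approx(
            np.exp(-0.827 * k ** 2 * a ** 2), rel=1e-12)

    def test_anderson_rayleigh_limit_normalized(self):
        assert anderson_form_factor(0.01, 50.0) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("diameter", [20.0, 60.0])
    def test_anderson_rayleigh_ka4_law(self, diameter):
        # ka <= 0.1: unnormalized cross-section follows the closed-form
        # Rayleigh amplitude within 1 %
        c, g, h = 1540.0, 1.02, 1.02
        a = 0.5 * diameter * 1e-6
        f = 0.1 * c / (2 * np.pi * a) / 1e6  # ka = 0.1
        x = 0.1
        sigma = unnormalized_fluid_sphere_cross_section(f, diameter, c, g, h)
        rayleigh = _rayleigh_backscatter_amplitude(x, g, h) ** 2
        assert sigma == pytest.approx(rayleigh, rel=0.01)

    def test_anderson_truncation_convergence(self):
        a1 = _fluid_sphere_backscatter_amplitude(2.0, 1.02, 1.02, tol=1e-10)
        a2 = _fluid_sphere_backscatter_amplitude(2.0, 1.02, 1.02, tol=1e-16)
        assert abs(a1 - a2) < 1e-8

    def test_anderson_extreme_ka_raises(self):
        with pytest.raises(ValueError):
            anderson_form_factor(400.0, 400.0)


class TestFitFormFactor:
    def _ref(self):
        f = np.linspace(0.0, 20.0, 401)
        return f, np.maximum(f, 1e-6) ** 4 * gaussian_form_factor(np.maximum(f, 1e-6), 20.0)

    def _ns_from_true_bsc(self, true_d, amp_lin=1.0):
        ref_f, ref_v = self._ref()
        f = np.linspace(0.0, 20.0, 401)
        bsc = amp_lin * np.maximum(f, 1e-6) ** 4 * gaussian_form_factor(np.maximum(f, 1e-6), true_d)
        vals = 10 * np.log10(bsc / ref_v)
        return NormalizedSpectrum(f, vals, window_depth=1.0)

    def test_noiseless_self_consistency(self):
        ns = self._ns_from_true_bsc(100.0)
        fit = fit_form_factor(ns, self._ref(), AnalysisBand(), model="gaussian")
        assert fit.ASD == pytest.approx(100.0, abs=0.5)
        assert fit.residual < 1e-8
        assert not fit.boundary

    def test_amplitude_shape_separation(self):
        f1 = fit_form_factor(self._ns_from_true_bsc(80.0, 1.0), self._ref(),
                             AnalysisBand(), model="gaussian")
        f2 = fit_form_factor(self._ns_from_true_bsc(80.0, 10.0), self._ref(),
                             AnalysisBand(), model="gaussian")
        assert f2.AAC - f1.AAC == pytest.approx(10.0, abs=1e-3)
        assert f2.ASD == pytest.approx(f1.ASD, abs=0.1)

    def test_boundary_flag(self):
        ns = self._ns_from_true_bsc(100.0)
        fit = fit_form_factor(ns, self._ref(), AnalysisBand(), model="gaussian",
                              diameter_bounds_um=(150.0, 300.0))
        assert fit.boundary

    def test_unknown_model_raises(self):
        with pytest.raises(ValueError):
            fit_form_factor(self._ns_from_true_bsc(80.0), self._ref(),
                            AnalysisBand(), model="spherical-cow")


class TestScaleConsistency:
    def test_rf_amplitude_scaling_moves_aac_not_asd(self, rng):
        # multiplying all RF amplitudes by s scales the power spectrum by
        # s^2, shifting the normalized spectrum by a constant dB offset
        f = np.linspace(0.0, 20.0, 401)
        ref_f = f
        ref_v = np.maximum(f, 1e-6) ** 4 * gaussian_form_factor(np.maximum(f, 1e-6), 20.0)
        base = 10 * np.log10(np.maximum(f, 1e-6) ** 4
                             * gaussian_form_factor(np.maximum(f, 1e-6), 90.0) / ref_v)
        noise = rng.normal(0, 0.5, size=f.size)
        for shift_db in (0.0, 20 * np.log10(3.0)):
            ns = NormalizedSpectrum(f, base + noise + shift_db, 1.0)
            fit = fit_form_factor(ns, (ref_f, ref_v), AnalysisBand(), "gaussian")
            if shift_db == 0.0:
                asd0, aac0 = fit.ASD, fit.AAC
            else:
                assert fit.ASD == pytest.approx(asd0, abs=1e-6)
                assert fit.AAC - aac0 == pytest.approx(shift_db, abs=1e-6)
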