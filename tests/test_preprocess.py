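import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from rbcspec.errors import ConfigError, InputError
from rbcspec.preprocess import (
    PreprocessConfig,
    atr_correct,
    normalize,
    preprocess_spectrum,
    remove_baseline,
    remove_cosmic_rays,
    savitzky_golay_smooth,
    second_derivative,
    default_config_for,
)
from rbcspec.spectra_io import Modality, Stage
from tests.conftest import make_spectrum


class TestConfig:
    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(sg_window=12)

    def test_window_vs_polyorder(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(sg_window=5, sg_polyorder=5)

    def test_bad_norm_range(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(norm_range=(3600.0, 900.0))

    def test_bad_baseline_method(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(baseline_method="wavelet")


class TestSmoothing:
    def test_quadratic_reproduced_exactly(self, ftir_config):
        x = np.arange(1000.0, 1200.0)
        y = 3e-4 * x**2 - 0.2 * x + 7.0
        s = make_spectrum(x, y)
        out = savitzky_golay_smooth(s, ftir_config)
        interior = slice(6, -6)
        np.testing.assert_allclose(out.intensities[interior], y[interior], atol=1e-9)

    def test_constant_unchanged(self, ftir_config):
        x = np.arange(100.0, 200.0)
        s = make_spectrum(x, np.full_like(x, 4.2))
        out = savitzky_golay_smooth(s, ftir_config)
        np.testing.assert_allclose(out.intensities, 4.2, atol=1e-12)

    def test_noise_variance_reduction_matches_coefficient_oracle(self, ftir_config):
        # oracle: white-noise variance after SG filtering is sum(c_i^2)
        c = savgol_coeffs(ftir_config.sg_window, ftir_config.sg_polyorder)
        expected_factor = float(np.sum(c**2))
        rng = np.random.default_rng(42)
        x = np.arange(10_000, dtype=float)
        y = rng.normal(0.0, 1.0, size=x.size)
        out = savitzky_golay_smooth(make_spectrum(x, y), ftir_config)
        interior = slice(13, -13)
        ratio = out.intensities[interior].var() / y[interior].var()
        assert ratio < 0.5
        assert ratio == pytest.approx(expected_factor, rel=0.05)

    def test_axis_preserved_bit_exact(self, ftir_config, gaussian_spectrum):
        out = savitzky_golay_smooth(gaussian_spectrum, ftir_config)
        assert out.wavenumbers is gaussian_spectrum.wavenumbers

    def test_short_spectrum_rejected(self, ftir_config):
        s = make_spectrum(np.arange(5.0), np.zeros(5))
        with pytest.raises(InputError, match="shorter"):
            savitzky_golay_smooth(s, ftir_config)

    def test_nonuniform_grid_rejected(self, ftir_config):
        x = np.concatenate([np.arange(0.0, 50.0), np.arange(50.0, 150.0, 2.0)])
        s = make_spectrum(x, np.zeros_like(x))
        with pytest.raises(InputError, match="uniform"):
            savitzky_golay_smooth(s, ftir_config)


class TestSecondDerivative:
    def test_quadratic_maps_to_constant(self, ftir_config):
        x = np.arange(0.0, 200.0)
        s = make_spectrum(x, x**2)
        out = second_derivative(s, ftir_config)
        assert out.stage == Stage.SECOND_DERIVATIVE
        np.testing.assert_allclose(out.intensities[10:-10], 2.0, atol=1e-6)

    def test_linear_maps_to_zero(self, ftir_config):
        x = np.arange(0.0, 200.0)
        s = make_spectrum(x, 5.0 * x + 3.0)
        out = second_derivative(s, ftir_config)
        np.testing.assert_allclose(out.intensities[10:-10], 0.0, atol=1e-9)

    def test_sine_closed_form(self, ftir_config):
        # d2/dx2 sin(wx) = -w^2 sin(wx); slow oscillation w*dx <= 0.05
        omega = 0.05
        x = np.arange(0.0, 2000.0)
        s = make_spectrum(x, np.sin(omega * x))
        out = second_derivative(s, ftir_config)
        expected = -(omega**2) * np.sin(omega * x)
        interior = slice(20, -20)
        scale = omega**2  # amplitude of the expected signal
        err = np.abs(out.intensities[interior] - expected[interior]).max()
        assert err <= 0.01 * scale

    def test_step_size_honored(self, ftir_config):
        # same parabola sampled at 0.5 cm^-1 must still give 2*alpha
        x = np.arange(0.0, 100.0, 0.5)
        s = make_spectrum(x, 3.0 * x**2)
        out = second_derivative(s, ftir_config)
        np.testing.assert_allclose(out.intensities[15:-15], 6.0, atol=1e-6)


class TestCosmicRays:
    def _smooth_raman(self, rng=None, noise_sd=1.0):
        x = np.arange(400.0, 1801.0)
        y = 50.0 + 100.0 * np.exp(-0.5 * ((x - 1000.0) / 30.0) ** 2)
        if rng is not None:
            y = y + rng.normal(0.0, noise_sd, size=x.size)
        return make_spectrum(x, y, modality=Modality.RAMAN)

    def test_single_spike_replaced_others_untouched(self, raman_config):
        rng = np.random.default_rng(3)
        s = self._smooth_raman(rng)
        spiked = s.intensities.copy()
        spiked[700] *= 50.0
        sp = make_spectrum(s.wavenumbers, spiked, modality=Modality.RAMAN)
        out = remove_cosmic_rays(sp, raman_config)
        assert out.meta["cosmic_flags"] == [700]
        keep = np.delete(np.arange(len(s)), [700])
        np.testing.assert_array_equal(out.intensities[keep], spiked[keep])
        # replacement close to the spike-free truth (within 2x local noise)
        assert abs(out.intensities[700] - s.intensities[700]) <= 2.0

    def test_spike_free_spectrum_unchanged(self, raman_config):
        rng = np.random.default_rng(4)
        s = self._smooth_raman(rng)
        out = remove_cosmic_rays(s, raman_config)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_two_adjacent_spikes_both_replaced(self, raman_config):
        rng = np.random.default_rng(5)
        s = self._smooth_raman(rng)
        spiked = s.intensities.copy()
        spiked[900] += 3000.0
        spiked[901] += 2000.0
        sp = make_spectrum(s.wavenumbers, spiked, modality=Modality.RAMAN)
        out = remove_cosmic_rays(sp, raman_config)
        assert set(out.meta["cosmic_flags"]) == {900, 901}
        for i in (900, 901):
            assert abs(out.intensities[i] - s.intensities[i]) <= 2.0

    def test_ftir_rejected(self, raman_config, gaussian_spectrum):
        with pytest.raises(InputError):
            remove_cosmic_rays(gaussian_spectrum, raman_config)

    def test_overflagging_returns_unchanged(self):
        cfg = PreprocessConfig(cosmic_z_threshold=0.01)
        rng = np.random.default_rng(6)
        x = np.arange(400.0, 700.0)
        s = make_spectrum(x, rng.normal(0, 1, x.size), modality=Modality.RAMAN)
        out = remove_cosmic_rays(s, cfg)
        np.testing.assert_array_equal(out.intensities, s.intensities)
        assert len(out.meta["cosmic_flags"]) > 0


class TestBaseline:
    def test_rubberband_on_linear_ramp_is_zero(self, raman_config):
        x = np.arange(400.0, 1801.0)
        s = make_spectrum(x, 0.3 * x + 12.0, modality=Modality.RAMAN)
        out = remove_baseline(s, raman_config)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)

    def test_gaussian_on_linear_baseline_area_recovered(self, raman_config):
        x = np.arange(400.0, 1801.0)
        sigma, amp, c = 5.0, 40.0, 1000.0
        band = amp * np.exp(-0.5 * ((x - c) / sigma) ** 2)
        s = make_spectrum(x, band + 0.1 * x + 30.0, modality=Modality.RAMAN)
        out = remove_baseline(s, raman_config)
        mask = (x >= c - 25) & (x <= c + 25)
        area = np.trapezoid(out.intensities[mask], x[mask])
        analytic = amp * sigma * np.sqrt(2 * np.pi)
        assert area == pytest.approx(analytic, rel=0.05)

    def test_baseline_free_spectrum_band_areas_stable(self, raman_config):
        x = np.arange(400.0, 1801.0)
        y = (
            40.0 * np.exp(-0.5 * ((x - 800.0) / 8.0) ** 2)
            + 60.0 * np.exp(-0.5 * ((x - 1400.0) / 10.0) ** 2)
        )
        s = make_spectrum(x, y, modality=Modality.RAMAN)
        out = remove_baseline(s, raman_config)
        for c, sig in ((800.0, 8.0), (1400.0, 10.0)):
            mask = (x >= c - 4 * sig) & (x <= c + 4 * sig)
            before = np.trapezoid(y[mask], x[mask])
            after = np.trapezoid(out.intensities[mask], x[mask])
            assert after == pytest.approx(before, rel=0.02)

    def test_poly_baseline_recovers_cubic(self):
        cfg = PreprocessConfig(baseline_method="poly", poly_degree=3)
        x = np.arange(400.0, 1801.0)
        base = 1e-8 * (x - 1000) ** 3 + 0.01 * x + 5.0
        band = 80.0 * np.exp(-0.5 * ((x - 1100.0) / 9.0) ** 2)
        s = make_spectrum(x, base + band, modality=Modality.RAMAN)
        out = remove_baseline(s, cfg)
        mask = (x >= 1060) & (x <= 1140)
        area = np.trapezoid(out.intensities[mask], x[mask])
        assert area == pytest.approx(80.0 * 9.0 * np.sqrt(2 * np.pi), rel=0.05)


class TestNormalize:
    def test_unit_norm_in_range(self, ftir_config, gaussian_spectrum):
        out = normalize(gaussian_spectrum, ftir_config)
        low, high = ftir_config.norm_range
        mask = (out.wavenumbers >= low) & (out.wavenumbers <= high)
        assert np.linalg.norm(out.intensities[mask]) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, ftir_config, gaussian_spectrum):
        scaled = gaussian_spectrum.with_intensities(7.3 * gaussian_spectrum.intensities)
        a = normalize(gaussian_spectrum, ftir_config)
        b = normalize(scaled, ftir_config)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-14)

    def test_zero_spectrum_error(self, ftir_config):
        s = make_spectrum(np.arange(900.0, 1000.0), np.zeros(100))
        with pytest.raises(InputError, match="zero"):
            normalize(s, ftir_config)

    def test_out_of_range_error(self, ftir_config):
        s = make_spectrum(np.arange(100.0, 200.0), np.ones(100))
        with pytest.raises(InputError, match="normalization range"):
            normalize(s, ftir_config)


class TestAtrCorrect:
    def setup_method(self):
        self.cfg = PreprocessConfig(atr_correction=True)

    def test_reference_wavenumber_fixed_point(self):
        x = np.arange(900.0, 3801.0)
        s = make_spectrum(x, np.ones_like(x))
        out = atr_correct(s, self.cfg)
        i = np.searchsorted(x, 1650.0)
        assert out.intensities[i] == pytest.approx(1.0)

    def test_double_at_twice_reference(self):
        x = np.arange(900.0, 3801.0)
        s = make_spectrum(x, np.ones_like(x))
        out = atr_correct(s, self.cfg)
        i = np.searchsorted(x, 3300.0)
        assert out.intensities[i] == pytest.approx(2.0)

    def test_flat_spectrum_proportional_to_wavenumber(self):
        x = np.arange(900.0, 3801.0)
        s = make_spectrum(x, np.full_like(x, 0.5))
        out = atr_correct(s, self.cfg)
        np.testing.assert_allclose(out.intensities, 0.5 * x / 1650.0)

    def test_raman_rejected(self):
        s = make_spectrum(np.arange(400.0, 500.0), np.ones(100), modality=Modality.RAMAN)
        with pytest.raises(InputError):
            atr_correct(s, self.cfg)


class TestFullChain:
    def test_stage_and_provenance(self, noisy_cohort):
        _, raw, _, _ = noisy_cohort
        s = raw.spectra[0]
        out = preprocess_spectrum(s, default_config_for(s.modality))
        assert out.stage == Stage.PREPROCESSED
        ops = [o["op"] for o in out.meta["ops"]]
        assert ops[-1] == "normalize"
        assert "savitzky_golay_smooth" in ops

    def test_raman_chain_order(self, noisy_cohort):
        _, raw, _, _ = noisy_cohort
        s = next(t for t in raw.spectra if t.modality == Modality.RAMAN)
        out = preprocess_spectrum(s, default_config_for(s.modality))
        ops = [o["op"] for o in out.meta["ops"]]
        assert ops.index("remove_cosmic_rays") < ops.index("savitzky_golay_smooth")
        assert ops.index("savitzky_golay_smooth") < ops.index("remove_baseline")
        assert ops.index("remove_baseline") < ops.index("normalize")

    def test_axis_bit_exact_through_chain(self, noisy_cohort):
        _, raw, _, _ = noisy_cohort
        for s in raw.spectra[:4]:
            out = preprocess_spectrum(s, default_config_for(s.modality))
            np.testing.assert_array_equal(out.wavenumbers, s.wavenumbers)
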