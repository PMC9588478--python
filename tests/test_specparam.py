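"""Spectral parameterizer: exact recovery, peak extraction, failure modes."""

import numpy as np
import pytest

from aperiodic import (
    FitParams,
    PSD,
    SimulationSpec,
    SpectralPeakSpec,
    aperiodic_component,
    constructed_spectrum,
    delta_sensitivity_experiment,
    fit_spectral_model,
)


def constructed_psd(spec, f_lo=1.0, f_hi=None):
    """Noiseless PSD on a 1 Hz grid straight from the construction recipe."""
    grid, dens = constructed_spectrum(spec)
    f_hi = f_hi or spec.f_sample / 2 - 1
    freqs = np.arange(f_lo, f_hi + 1.0)
    return PSD(freqs, np.interp(freqs, grid, dens))


class TestAperiodicRecovery:
    def test_exact_power_law_beta2(self, power_law_psd):
        model = fit_spectral_model(power_law_psd(2.0),
                                   FitParams(fit_range=(1, 100)))
        assert model.aperiodic.exponent == pytest.approx(2.0, abs=1e-6)
        assert len(model.peaks) == 0

    @pytest.mark.parametrize("beta", [0.5, 1.0, 1.5, 2.0, 3.0])
    def test_power_law_recovery_to_1e3(self, power_law_psd, beta):
        model = fit_spectral_model(power_law_psd(beta),
                                   FitParams(fit_range=(1, 100)))
        assert model.aperiodic.exponent == pytest.approx(beta, abs=1e-3)

    def test_knee_mode_recovers_knee_spectrum(self):
        freqs = np.arange(1.0, 201.0)
        knee, chi, off = 25.0, 2.0, -1.0
        psd = PSD(freqs, 10.0 ** (off - np.log10(knee + freqs**chi)))
        model = fit_spectral_model(
            psd, FitParams(fit_range=(1, 200), aperiodic_mode="knee"))
        assert model.aperiodic.exponent == pytest.approx(chi, abs=0.01)
        assert model.aperiodic.knee == pytest.approx(knee, rel=0.05)

    def test_fixed_mode_has_no_knee(self, power_law_psd):
        model = fit_spectral_model(power_law_psd(1.0),
                                   FitParams(fit_range=(1, 100)))
        assert model.aperiodic.knee is None


class TestPeakExtraction:
    def test_single_peak_recovery(self):
        # moderate amplitude: log10(1 + A g) stays close to Gaussian, so a
        # single component suffices (tall peaks saturate in log power and
        # legitimately decompose into several Gaussians)
        spec = SimulationSpec(beta=1.0, duration_s=180, f_sample=2400,
                              peaks=(SpectralPeakSpec(10.0, 1.0, 1.5),))
        model = fit_spectral_model(constructed_psd(spec, 1, 100),
                                   FitParams(fit_range=(1, 100)))
        assert len(model.peaks) == 1
        assert model.peaks[0].cf == pytest.approx(10.0, abs=0.5)
        assert model.aperiodic.exponent == pytest.approx(1.0, abs=0.05)

    def test_bw_is_twice_sigma_squared(self):
        spec = SimulationSpec(beta=1.0, duration_s=180, f_sample=2400,
                              peaks=(SpectralPeakSpec(10.0, 1.0, 1.5),))
        model = fit_spectral_model(constructed_psd(spec, 1, 100),
                                   FitParams(fit_range=(1, 100)))
        p = model.peaks[0]
        assert p.bw == pytest.approx(2.0 * p.sigma**2)

    def test_flattened_residual_maxima_at_generated_peaks(self):
        cfs = (8.0, 20.0, 40.0)
        spec = SimulationSpec(
            beta=1.5, duration_s=180, f_sample=2400,
            peaks=tuple(SpectralPeakSpec(cf, 4.0, 1.0) for cf in cfs))
        psd = constructed_psd(spec, 1, 100)
        model = fit_spectral_model(psd, FitParams(fit_range=(1, 100),
                                                  max_n_peaks=0))
        residual = np.log10(psd.power) - aperiodic_component(model, psd.freqs)
        for cf in cfs:
            near = np.abs(psd.freqs - cf) <= 1.0
            far = (np.abs(psd.freqs - cf) > 3.0) & (np.abs(psd.freqs - cf) < 6)
            assert residual[near].max() > residual[far].max()

    def test_threshold_monotonicity(self, peaky_series):
        from aperiodic import welch_psd

        psd = welch_psd(peaky_series, segment_s=1.0)
        counts = []
        for thresh in (1.0, 1.5, 2.0, 3.0, 5.0):
            model = fit_spectral_model(
                psd, FitParams(fit_range=(1, 100), peak_threshold=thresh))
            counts.append(len(model.peaks))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_max_n_peaks_zero_fits_nothing(self, peaky_series):
        from aperiodic import welch_psd

        psd = welch_psd(peaky_series, segment_s=1.0)
        model = fit_spectral_model(psd, FitParams(fit_range=(1, 100),
                                                  max_n_peaks=0))
        assert model.peaks == ()

    def test_troughs_are_never_fitted(self, power_law_psd):
        psd = power_law_psd(1.0)
        notched = psd.power.copy()
        notched[48:52] *= 0.2  # spectral dip, e.g. a notch filter
        model = fit_spectral_model(PSD(psd.freqs, notched),
                                   FitParams(fit_range=(1, 100)))
        assert all(p.pw > 0 for p in model.peaks)
        assert not any(45 <= p.cf <= 55 for p in model.peaks)


class TestAperiodicComponent:
    def test_fixed_form_arithmetic(self, power_law_psd):
        model = fit_spectral_model(power_law_psd(2.0),
                                   FitParams(fit_range=(1, 100)))
        # offset ~ 0, exponent ~ 2 -> value at 10 Hz is -2 in log10 power
        assert aperiodic_component(model, [10.0])[0] == pytest.approx(-2.0,
                                                                      abs=1e-5)

    def test_equals_input_for_pure_power_law(self, power_law_psd):
        psd = power_law_psd(1.7)
        model = fit_spectral_model(psd, FitParams(fit_range=(1, 100)))
        np.testing.assert_allclose(
            aperiodic_component(model, psd.freqs), np.log10(psd.power),
            atol=1e-6)

    def test_rejects_nonpositive_frequency(self, power_law_psd):
        model = fit_spectral_model(power_law_psd(1.0),
                                   FitParams(fit_range=(1, 100)))
        with pytest.raises(ValueError):
            aperiodic_component(model, [0.0, 10.0])


class TestErrors:
    def test_nonpositive_power_rejected(self):
        psd = PSD(np.arange(1.0, 50.0), np.zeros(49))
        with pytest.raises(ValueError, match="positive"):
            fit_spectral_model(psd, FitParams(fit_range=(1, 40)))

    def test_narrow_range_rejected(self, power_law_psd):
        with pytest.raises(ValueError, match="3"):
            fit_spectral_model(power_law_psd(1.0),
                               FitParams(fit_range=(10, 11)))

    def test_constant_spectrum_reports_singular_fit(self):
        psd = PSD(np.arange(1.0, 50.0), np.ones(49))
        with pytest.raises(ValueError, match="singular"):
            fit_spectral_model(psd, FitParams(fit_range=(1, 40)))

    def test_range_not_covered_rejected(self, power_law_psd):
        with pytest.raises(ValueError, match="cover"):
            fit_spectral_model(power_law_psd(1.0, 1, 50),
                               FitParams(fit_range=(1, 200)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FitParams(fit_range=(10, 5))
        with pytest.raises(ValueError):
            FitParams(fit_range=(1, 100), peak_width_limits=(3.0, 1.0))
        with pytest.raises(ValueError):
            FitParams(fit_range=(1, 100), aperiodic_mode="bogus")


class TestDeltaSensitivity:
    def test_empty_scales_give_empty_table(self):
        base = SimulationSpec(beta=1.5, duration_s=10, f_sample=600,
                              peaks=(SpectralPeakSpec(2.0, 4.0, 1.0),))
        table = delta_sensitivity_experiment(base, [])
        assert len(table) == 0

    def test_interior_peak_is_scale_insensitive(self):
        """A narrow peak well inside the range leaves the fit unchanged."""
        base = SimulationSpec(beta=1.5, duration_s=120, f_sample=1200,
                              peaks=(SpectralPeakSpec(20.0, 3.0, 0.8),),
                              seed=2)
        table = delta_sensitivity_experiment(
            base, (0.0, 1.0, 2.0),
            fit_params=FitParams(fit_range=(1.0, 95.0)))
        est = table["beta_est"].to_numpy()
        assert np.all(np.isfinite(est))
        assert est.max() - est.min() < 0.05

    def test_truth_constant_across_rows(self):
        base = SimulationSpec(beta=1.5, duration_s=10, f_sample=600,
                              peaks=(SpectralPeakSpec(2.0, 4.0, 1.0),))
        table = delta_sensitivity_experiment(base, (0.0, 1.0))
        assert set(table["beta_truth"]) == {1.5}


def test_model_serialization(tmp_path, power_law_psd):
    model = fit_spectral_model(power_law_psd(2.0),
                               FitParams(fit_range=(1, 100)))
    path = tmp_path / "model.txt"
    model.save(path)
    text = path.read_text()
    assert "exponent" in text and "cf pw bw" in text
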