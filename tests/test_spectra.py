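import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opsinkit.spectra import (
    LambdaMaxEstimate,
    Spectrum,
    SpectralMeasurement,
    average_spectra,
    difference_spectrum,
    estimate_lambda_max,
    fit_smoothing_spline,
    read_measurement_csv,
    welch_t_test,
    write_measurement_csv,
)
from opsinkit.spectra.core import GridMismatchError
from opsinkit.synthgen import PigmentTemplateParams, simulate_measurement
from opsinkit.synthgen.pigment import bleach_component, pigment_component

WL = np.arange(250.0, 701.0)


def _spectrum(values, condition="dark", rep=None):
    return Spectrum(WL, values, condition, rep)


class TestAverageSpectra:
    def test_single_scan_identity(self):
        s = _spectrum(np.sin(WL / 40.0))
        out = average_spectra([s])
        np.testing.assert_array_equal(out.absorbances, s.absorbances)

    def test_opposite_scans_cancel(self):
        v = np.cos(WL / 25.0)
        out = average_spectra([_spectrum(v), _spectrum(-v)])
        np.testing.assert_allclose(out.absorbances, 0.0, atol=1e-15)

    def test_noise_free_replicates_equal_single_scan(self):
        p = PigmentTemplateParams(lambda_max=500.0, noise_sd=0.0,
                                  n_replicates=8, seed=0)
        m = simulate_measurement(p)
        mean = average_spectra(m.dark_scans)
        np.testing.assert_allclose(
            mean.absorbances, m.dark_scans[0].absorbances, atol=1e-14
        )

    def test_grid_mismatch(self):
        other = Spectrum(WL + 1.0, np.zeros_like(WL), "dark")
        with pytest.raises(GridMismatchError):
            average_spectra([_spectrum(np.zeros_like(WL)), other])

    def test_empty_list(self):
        with pytest.raises(ValueError):
            average_spectra([])


class TestDifferenceSpectrum:
    def test_identical_scans_zero(self):
        v = np.exp(-((WL - 500.0) ** 2) / 5000.0)
        d = difference_spectrum(_spectrum(v, "dark"), _spectrum(v, "light"))
        np.testing.assert_allclose(d.absorbances, 0.0, atol=1e-15)
        assert d.condition == "difference"

    def test_full_bleach_algebra(self):
        p = PigmentTemplateParams(lambda_max=443.0, noise_sd=0.0,
                                  bleach_fraction=1.0, n_replicates=1, seed=0)
        m = simulate_measurement(p)
        d = difference_spectrum(m.dark_scans[0], m.light_scans[0])
        expected = pigment_component(p) - bleach_component(p)
        np.testing.assert_allclose(d.absorbances, expected, atol=1e-12)

    def test_linearity_of_means(self):
        p = PigmentTemplateParams(lambda_max=500.0, noise_sd=0.01,
                                  n_replicates=6, seed=4)
        m = simulate_measurement(p)
        diff_of_means = difference_spectrum(
            average_spectra(m.dark_scans),
            average_spectra(m.light_scans),
        )
        per_rep = [
            difference_spectrum(d, l)
            for d, l in zip(m.dark_scans, m.light_scans)
        ]
        mean_of_diffs = average_spectra(per_rep)
        np.testing.assert_allclose(
            diff_of_means.absorbances, mean_of_diffs.absorbances, atol=1e-12
        )

    def test_condition_enforced(self):
        v = np.zeros_like(WL)
        with pytest.raises(ValueError):
            difference_spectrum(_spectrum(v, "light"), _spectrum(v, "light"))


class TestSmoothingSpline:
    def test_linear_data_reproduced_any_smoothness(self):
        # straight lines span the null space of the curvature penalty
        y = 0.003 * WL + 1.0
        for smoothness in (0.0, 0.5, 0.9, 1.0):
            fit = fit_smoothing_spline(_spectrum(y), smoothness=smoothness)
            np.testing.assert_allclose(fit(WL), y, atol=1e-8)

    def test_noise_free_template_small_residual(self):
        p = PigmentTemplateParams(lambda_max=500.0, noise_sd=0.0,
                                  n_replicates=1, seed=0)
        m = simulate_measurement(p)
        fit = fit_smoothing_spline(m.dark_scans[0], edf=120.0)
        resid = np.max(np.abs(fit(WL) - m.dark_scans[0].absorbances))
        assert resid < 0.01 * p.alpha_amplitude

    def test_rss_nondecreasing_in_smoothness(self):
        rng = np.random.default_rng(0)
        y = np.exp(-((WL - 480.0) ** 2) / 3000.0) + rng.normal(0, 0.05, WL.size)
        spec = _spectrum(y)
        rss = [
            fit_smoothing_spline(spec, smoothness=s).residual_ss
            for s in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_too_few_points(self):
        s = Spectrum(np.arange(5.0), np.zeros(5), "dark")
        with pytest.raises(ValueError):
            fit_smoothing_spline(s)


class TestEstimateLambdaMax:
    def test_noise_free_sws2_dark(self):
        p = PigmentTemplateParams(lambda_max=443.0, noise_sd=0.0,
                                  n_replicates=2, seed=0)
        m = simulate_measurement(p)
        est = estimate_lambda_max(m, "dark_spectrum", (380.0, 520.0))
        assert abs(est.mean_nm - 443.0) < 1.0
        assert est.sd_nm == 0.0

    def test_noisy_replicates_recover_truth(self):
        p = PigmentTemplateParams(lambda_max=443.0, noise_sd=0.002,
                                  n_replicates=8, seed=11)
        m = simulate_measurement(p)
        est = estimate_lambda_max(m, "dark_spectrum", (380.0, 520.0))
        assert est.sd_nm > 0.0
        assert abs(est.mean_nm - 443.0) < 3.0
        assert est.n == 8

    def test_estimator_consistency_across_smoothness(self):
        p = PigmentTemplateParams(lambda_max=500.0, noise_sd=0.0,
                                  n_replicates=1, seed=0)
        m = simulate_measurement(p)
        for edf in (20.0, 45.0, 90.0):
            est = estimate_lambda_max(m, "dark_spectrum", (420.0, 580.0),
                                      edf=edf)
            assert abs(est.mean_nm - 500.0) <= 1.0

    def test_difference_exceeds_dark_for_short_wave_pigment(self):
        # 380-nm bleach product drags the difference-spectrum peak of a
        # 443-nm pigment to longer wavelengths than the dark estimate
        p = PigmentTemplateParams(lambda_max=443.0, noise_sd=0.0,
                                  bleach_fraction=1.0, n_replicates=2, seed=0)
        m = simulate_measurement(p)
        dark = estimate_lambda_max(m, "dark_spectrum", (380.0, 520.0))
        diff = estimate_lambda_max(m, "difference_spectrum", (380.0, 520.0))
        assert diff.mean_nm - dark.mean_nm >= 2.0

    def test_mean_sd_recomputable(self):
        p = PigmentTemplateParams(lambda_max=500.0, noise_sd=0.003,
                                  n_replicates=8, seed=2)
        m = simulate_measurement(p)
        est = estimate_lambda_max(m, "dark_spectrum", (420.0, 580.0))
        assert est.mean_nm == pytest.approx(
            float(np.mean(est.per_replicate_peaks)), abs=0
        )
        assert est.sd_nm == pytest.approx(
            float(np.std(est.per_replicate_peaks, ddof=1)), abs=0
        )
        assert all(
            est.search_window[0] <= pk <= est.search_window[1]
            for pk in est.per_replicate_peaks
        )

    def test_monotone_curve_flagged(self):
        y = 0.001 * WL
        m = SpectralMeasurement("mono", [Spectrum(WL, y, "dark", 1)])
        with pytest.warns(UserWarning):
            est = estimate_lambda_max(m, "dark_spectrum", (400.0, 600.0))
        assert est.boundary_peak
        assert est.mean_nm == pytest.approx(600.0)

    def test_difference_requires_light_scans(self):
        m = SpectralMeasurement("d", [_spectrum(np.zeros_like(WL), "dark", 1)])
        with pytest.raises(ValueError):
            estimate_lambda_max(m, "difference_spectrum", (400.0, 600.0))


class TestWelch:
    def test_identical_groups(self):
        r = welch_t_test((500.0, 2.0, 8), (500.0, 2.0, 8))
        assert r.t_statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_printed_sws2_comparison(self):
        # textbook-formula verification: t = 9.1/sqrt(3.9^2/8 + 0.8^2/8)
        r = welch_t_test((451.7, 3.9, 8), (442.6, 0.8, 8))
        assert 1e-4 <= r.p_value <= 5e-4
        assert round(r.p_value, 4) in (0.0002, 0.0003)

    def test_printed_lws_comparison(self):
        r = welch_t_test((570.2, 14.8, 8), (560.6, 9.4, 8))
        assert r.p_value == pytest.approx(0.15, abs=0.01)

    def test_raw_equals_summary(self):
        rng = np.random.default_rng(3)
        a = rng.normal(500, 3, 8)
        b = rng.normal(505, 5, 8)
        r_raw = welch_t_test(a, b)
        r_sum = welch_t_test(
            (np.mean(a), np.std(a, ddof=1), 8),
            (np.mean(b), np.std(b, ddof=1), 8),
        )
        assert r_raw.t_statistic == pytest.approx(r_sum.t_statistic, rel=1e-12)
        assert r_raw.p_value == pytest.approx(r_sum.p_value, rel=1e-12)

    def test_accepts_estimates(self):
        e1 = LambdaMaxEstimate.from_peaks(
            "dark_spectrum", [500.0, 501.0, 502.0], (450, 550)
        )
        e2 = LambdaMaxEstimate.from_peaks(
            "dark_spectrum", [510.0, 511.0, 512.0], (450, 550)
        )
        r = welch_t_test(e1, e2)
        assert r.p_value < 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test((500.0, 1.0, 1), (501.0, 1.0, 8))

    @given(
        st.lists(st.floats(400, 600), min_size=4, max_size=10),
        st.lists(st.floats(400, 600), min_size=4, max_size=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_welch_formula_property(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            return
        r = welch_t_test(a, b)
        v1 = np.var(a, ddof=1) / a.size
        v2 = np.var(b, ddof=1) / b.size
        t = (np.mean(a) - np.mean(b)) / np.sqrt(v1 + v2)
        assert r.t_statistic == pytest.approx(t, rel=1e-9, abs=1e-9)
        assert 0.0 <= r.p_value <= 1.0


class TestIO:
    def test_roundtrip(self, tmp_path):
        p = PigmentTemplateParams(lambda_max=500.0, noise_sd=0.002,
                                  n_replicates=3, seed=1)
        m = simulate_measurement(p)
        path = tmp_path / "scan.csv"
        write_measurement_csv(m, path)
        back = read_measurement_csv(path)
        assert len(back.dark_scans) == 3
        assert len(back.light_scans) == 3
        np.testing.assert_allclose(
            back.dark_scans[0].absorbances, m.dark_scans[0].absorbances
        )

    def test_bare_two_column(self, tmp_path):
        path = tmp_path / "bare.csv"
        path.write_text(
            "wavelength,absorbance\n"
            + "\n".join(f"{w},{0.01 * i}" for i, w in enumerate(range(400, 420)))
        )
        m = read_measurement_csv(path)
        assert len(m.dark_scans) == 1
        assert m.dark_scans[0].wavelengths[0] == 400.0
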