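"""Inner-filter correction, Stern-Volmer fitting and quench-mode calls."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specbind import (PipelineConfig, QuenchingResult, Spectrum,
                      classify_quench_mode, fit_stern_volmer,
                      inner_filter_correct, peak_intensity, summarize_ans)
from specbind.quenching import DIFFUSION_LIMIT_KQ

from conftest import series_from_intensities

TAU0 = 5.78e-9


class TestInnerFilter:
    @pytest.mark.parametrize("F,a_ex,a_em,base,expected", [
        (100.0, 0.0, 0.0, "e", 100.0),
        (100.0, 0.1, 0.1, "e", 100.0 * math.e**0.1),      # 110.517...
        (100.0, 0.1, 0.1, "ten", 100.0 * 10**0.1),        # 125.893...
    ])
    def test_correction_values(self, F, a_ex, a_em, base, expected):
        assert inner_filter_correct(F, a_ex, a_em, base) == pytest.approx(
            expected, rel=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            inner_filter_correct(100.0, -0.1, 0.0)

    @given(F=st.floats(0.1, 1e6), a=st.floats(0, 2), b=st.floats(0, 2))
    def test_multiplicative_in_intensity(self, F, a, b):
        full = inner_filter_correct(F, a, b)
        unit = inner_filter_correct(1.0, a, b)
        assert full == pytest.approx(F * unit, rel=1e-12)

    @given(a1=st.floats(0, 2), a2=st.floats(0, 2), delta=st.floats(0.01, 1))
    def test_monotone_in_total_absorbance(self, a1, a2, delta):
        lo = inner_filter_correct(100.0, a1, a2)
        hi = inner_filter_correct(100.0, a1 + delta, a2)
        assert hi > lo


class TestPeakIntensity:
    def test_gaussian_band_read_at_center(self):
        wl = np.arange(290.0, 451.0)
        s = Spectrum(wl, 100.0 * np.exp(-0.5 * ((wl - 335.0) / 25.0) ** 2))
        assert peak_intensity(s, at_nm=335.0) == pytest.approx(100.0)
        assert s.peak_wavelength_nm == 335.0

    def test_flat_spectrum(self):
        s = Spectrum([290.0, 450.0], [5.0, 5.0])
        assert peak_intensity(s) == 5.0

    def test_global_max_on_bimodal(self):
        s = Spectrum([300.0, 320.0, 340.0, 360.0], [1.0, 8.0, 2.0, 10.0])
        assert peak_intensity(s) == 10.0

    def test_fixed_wavelength_outside_grid_raises(self):
        s = Spectrum([290.0, 450.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            peak_intensity(s, at_nm=500.0)


class TestSternVolmer:
    def test_noise_free_recovery(self, sv_series):
        series, ksv = sv_series
        q = fit_stern_volmer(series)
        assert q.Ksv_per_M == pytest.approx(ksv, rel=1e-9)
        assert q.intercept == pytest.approx(1.0, abs=1e-9)
        assert q.r_squared == pytest.approx(1.0, abs=1e-12)
        assert q.mode == "inconclusive"

    def test_kq_is_exact_quotient(self, sv_series):
        series, ksv = sv_series
        q = fit_stern_volmer(series, PipelineConfig(tau0_s=TAU0))
        assert q.kq_per_M_s == q.Ksv_per_M / TAU0

    def test_kq_scales_inversely_with_tau0(self, sv_series):
        series, _ = sv_series
        q1 = fit_stern_volmer(series, PipelineConfig(tau0_s=TAU0))
        q2 = fit_stern_volmer(series, PipelineConfig(tau0_s=2 * TAU0))
        assert q2.kq_per_M_s == pytest.approx(q1.kq_per_M_s / 2, rel=1e-12)

    def test_fixed_intercept_option(self, sv_series):
        series, ksv = sv_series
        q = fit_stern_volmer(series, PipelineConfig(sv_intercept="fixed"))
        assert q.intercept == 1.0
        assert q.Ksv_per_M == pytest.approx(ksv, rel=1e-9)

    def test_constant_intensity_flagged(self):
        series = series_from_intensities(
            [0.0, 5e-6, 1e-5], [100.0, 100.0, 100.0])
        q = fit_stern_volmer(series)
        assert q.Ksv_per_M == 0.0
        assert q.flagged

    def test_band_and_peak_readings_agree_on_noise_free_data(self, sv_series):
        series, ksv = sv_series
        q_band = fit_stern_volmer(series, PipelineConfig(intensity_mode="band"))
        q_peak = fit_stern_volmer(series, PipelineConfig(intensity_mode="peak"))
        assert q_band.Ksv_per_M == pytest.approx(q_peak.Ksv_per_M, rel=1e-12)

    def test_inner_filter_correction_recovers_true_ksv(self):
        # attenuate "measured" intensities; absorbances stored per point
        ksv = 7.16e4
        concs = np.array([0.0, 5e-6, 1e-5, 1.5e-5])
        F_true = 1000.0 / (1.0 + ksv * concs)
        absorb = [(0.02 * i, 0.01 * i) for i in range(len(concs))]
        F_meas = [f * math.e ** (-(a + b) / 2)
                  for f, (a, b) in zip(F_true, absorb)]
        series = series_from_intensities(concs, F_meas, absorbances=absorb)
        q = fit_stern_volmer(series)
        assert q.Ksv_per_M == pytest.approx(ksv, rel=1e-9)


class TestModeClassification:
    @staticmethod
    def _result(T, ksv, kq):
        return QuenchingResult(T, ksv, 1.0, 1.0, kq, TAU0)

    def test_high_kq_and_falling_ksv_is_static(self):
        results = [self._result(298, 7.16e4, 1.25e13),
                   self._result(303, 5.54e4, 0.97e13),
                   self._result(308, 4.06e4, 0.71e13)]
        mode, evidence = classify_quench_mode(results)
        assert mode == "static"
        assert "decreasing" in evidence

    def test_low_kq_and_rising_ksv_is_dynamic(self):
        results = [self._result(298, 1e4, 1e9),
                   self._result(308, 2e4, 2e9)]
        assert classify_quench_mode(results)[0] == "dynamic"

    def test_conflicting_criteria_inconclusive(self):
        results = [self._result(298, 1e4, 1e13),
                   self._result(308, 2e4, 2e13)]  # kq high but Ksv rising
        assert classify_quench_mode(results)[0] == "inconclusive"

    def test_threshold_is_strict(self):
        results = [self._result(298, 2e4, DIFFUSION_LIMIT_KQ)]
        # kq exactly at the collisional limit is not "higher than" it
        assert classify_quench_mode(results)[0] == "dynamic"

    def test_order_invariance(self):
        results = [self._result(298, 7.16e4, 1.25e13),
                   self._result(303, 5.54e4, 0.97e13),
                   self._result(308, 4.06e4, 0.71e13)]
        forward = classify_quench_mode(results)
        backward = classify_quench_mode(list(reversed(results)))
        shuffled = classify_quench_mode([results[1], results[2], results[0]])
        assert forward == backward == shuffled

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_quench_mode([])


class TestAnsSummary:
    def test_saturation_at_first_settled_step(self):
        concs = [0.0, 5e-6, 1e-5, 1.5e-5, 2e-5]
        series = series_from_intensities(concs, [100.0, 60.0, 40.0, 39.5, 39.4])
        res = summarize_ans(series, tolerance=0.01)
        assert res.saturation_conc_M == pytest.approx(1.5e-5)
        assert res.relative_intensity[0] == 1.0

    def test_linear_decrease_never_saturates(self):
        concs = [0.0, 5e-6, 1e-5, 1.5e-5, 2e-5]
        series = series_from_intensities(concs, [100.0, 90.0, 80.0, 70.0, 60.0])
        assert summarize_ans(series, tolerance=0.01).saturation_conc_M is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            series = series_from_intensities([0.0, 1e-6], [100.0, 90.0])
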