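"""Bragg-series fitting, lamellar spacing, Lorentz correction, chain peak."""

import numpy as np
import pytest

from memdiff.peakfit import (
    SQRT2PI,
    Axis,
    BraggPeak,
    FormFactorSet,
    IntensityCurve,
    chain_peak,
    fit_bragg_series,
    form_factor_magnitudes,
    lamellar_spacing,
)
from memdiff.synthetic import analytic_form_factors, simulate_intensity_curve


def _gauss(q, center, sigma, height):
    return height * np.exp(-((q - center) ** 2) / (2 * sigma**2))


class TestIntensityCurve:
    def test_non_ascending_q_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            IntensityCurve(Axis.OUT_OF_PLANE, [0.1, 0.1, 0.2], [1, 1, 1])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            IntensityCurve(Axis.OUT_OF_PLANE, [0.1, 0.2], [1, -1])

    def test_error_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="error"):
            IntensityCurve(Axis.OUT_OF_PLANE, [0.1, 0.2], [1, 1], [1.0])


class TestBraggPeak:
    def test_area_identity_auto(self):
        p = BraggPeak(order=1, center=0.114, sigma=0.002, amplitude=1000.0,
                      background=(0.0, 0.0))
        assert p.area == pytest.approx(1000.0 * 0.002 * SQRT2PI, rel=1e-12)

    def test_inconsistent_area_rejected(self):
        with pytest.raises(ValueError, match="area"):
            BraggPeak(order=1, center=0.1, sigma=0.002, amplitude=1000.0,
                      background=(0.0, 0.0), area=1.0)

    def test_bad_order_and_sigma_rejected(self):
        with pytest.raises(ValueError):
            BraggPeak(order=0, center=0.1, sigma=0.002, amplitude=1.0,
                      background=(0.0, 0.0))
        with pytest.raises(ValueError):
            BraggPeak(order=1, center=0.1, sigma=0.0, amplitude=1.0,
                      background=(0.0, 0.0))


class TestFitBraggSeries:
    def test_noiseless_single_gaussian_recovered(self):
        center, sigma, height = 0.114, 0.002, 1000.0
        q = np.linspace(0.08, 0.15, 4001)
        y = 10.0 + _gauss(q, center, sigma, height)
        curve = IntensityCurve(Axis.OUT_OF_PLANE, q, y)
        peaks = fit_bragg_series(curve, d_hint=2 * np.pi / center, max_order=1,
                                 sigma_guess=sigma)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.center == pytest.approx(center, rel=1e-6)
        assert p.sigma == pytest.approx(sigma, rel=1e-6)
        assert p.amplitude == pytest.approx(height, rel=1e-6)

    def test_seeded_series_centers_within_half_sigma(self, gel_model):
        ffs = analytic_form_factors(gel_model, 10)
        curve = simulate_intensity_curve(ffs, 0.01, (0.0, 50.0), seed=7)
        peaks = fit_bragg_series(curve, d_hint=gel_model.d_spacing)
        assert peaks, "strong orders must be detected"
        for p in peaks:
            q_true = 2 * np.pi * p.order / gel_model.d_spacing
            assert abs(p.center - q_true) < 0.5 * 0.004

    def test_flat_curve_empty_with_warning(self):
        q = np.linspace(0.05, 1.0, 2000)
        curve = IntensityCurve(Axis.OUT_OF_PLANE, q, np.full_like(q, 20.0))
        with pytest.warns(UserWarning, match="noise floor"):
            peaks = fit_bragg_series(curve)
        assert peaks == []

    def test_wrong_axis_rejected(self):
        q = np.linspace(1.0, 1.8, 100)
        curve = IntensityCurve(Axis.IN_PLANE, q, np.ones_like(q))
        with pytest.raises(ValueError, match="out-of-plane"):
            fit_bragg_series(curve)


class TestLamellarSpacing:
    @staticmethod
    def _peaks_for(d, orders):
        return [BraggPeak(order=n, center=2 * np.pi * n / d, sigma=0.002,
                          amplitude=100.0, background=(0.0, 0.0))
                for n in orders]

    def test_five_orders_recover_spacing(self):
        assert lamellar_spacing(self._peaks_for(55.07, range(1, 6))) == \
            pytest.approx(55.07, rel=1e-12)

    def test_single_peak(self):
        assert lamellar_spacing(self._peaks_for(69.0, [1])) == \
            pytest.approx(69.0, rel=1e-12)

    def test_outlier_rejected(self):
        peaks = self._peaks_for(2 * np.pi / 0.1, [1, 2, 4, 5])
        peaks.append(BraggPeak(order=3, center=0.5, sigma=0.002,
                               amplitude=100.0, background=(0.0, 0.0)))
        with pytest.raises(ValueError, match="inconsistent"):
            lamellar_spacing(peaks)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lamellar_spacing([])

    def test_scale_equivariance(self):
        d = 55.07
        base = lamellar_spacing(self._peaks_for(d, range(1, 6)))
        for c in (0.5, 2.0, 3.7):
            scaled = lamellar_spacing(self._peaks_for(d / c, range(1, 6)))
            assert scaled == pytest.approx(base / c, rel=1e-12)


class TestFormFactorMagnitudes:
    @staticmethod
    def _peak(order, area, d=55.07):
        sigma = 0.002
        return BraggPeak(order=order, center=2 * np.pi * order / d, sigma=sigma,
                         amplitude=area / (sigma * SQRT2PI), background=(0.0, 0.0))

    def test_zero_area_gives_zero_magnitude(self):
        # an amplitude of ~0 peak (degenerate but legal input path)
        ffs = form_factor_magnitudes([self._peak(1, 1e-30)], 55.07)
        assert ffs.magnitudes[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_areas_scale_as_sqrt_q(self):
        ffs = form_factor_magnitudes([self._peak(1, 10.0), self._peak(2, 10.0)],
                                     55.07)
        assert ffs.magnitudes[1] / ffs.magnitudes[0] == \
            pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_negative_area_clipped_with_warning(self):
        sigma = 0.002
        bad = BraggPeak(order=1, center=0.114, sigma=sigma, amplitude=-5.0,
                        background=(0.0, 0.0))
        with pytest.warns(UserWarning, match="negative"):
            ffs = form_factor_magnitudes([bad], 55.07)
        assert ffs.magnitudes[0] == 0.0

    def test_lorentz_monotone_in_q(self):
        peaks = [self._peak(n, 10.0) for n in range(1, 9)]
        ffs = form_factor_magnitudes(peaks, 55.07)
        assert np.all(np.diff(ffs.magnitudes) > 0)

    def test_exponent_option(self):
        peaks = [self._peak(2, 10.0)]
        e1 = form_factor_magnitudes(peaks, 55.07, lorentz_exponent=1.0)
        eh = form_factor_magnitudes(peaks, 55.07, lorentz_exponent=0.5)
        q = 2 * np.pi * 2 / 55.07
        assert e1.magnitudes[0] / eh.magnitudes[0] == \
            pytest.approx(q**0.25, rel=1e-12)

    def test_noiseless_round_trip_within_one_percent(self, gel_model):
        ffs_true = analytic_form_factors(gel_model, 10)
        curve = simulate_intensity_curve(ffs_true, 0.0, (0.0, 50.0), seed=1)
        peaks = fit_bragg_series(curve, d_hint=gel_model.d_spacing)
        d = lamellar_spacing(peaks)
        ffs = form_factor_magnitudes(peaks, d)
        for order, mag in zip(ffs.orders, ffs.magnitudes):
            truth = ffs_true.magnitudes[list(ffs_true.orders).index(order)]
            assert mag == pytest.approx(truth, rel=0.01)


class TestFormFactorSet:
    def test_orders_must_ascend(self):
        with pytest.raises(ValueError, match="ascending"):
            FormFactorSet(55.0, [2, 1], [1.0, 1.0])

    def test_q_consistent_with_d(self):
        ffs = FormFactorSet(55.07, [1, 2, 3], [1.0, 1.0, 1.0])
        assert np.allclose(ffs.q, 2 * np.pi * np.array([1, 2, 3]) / 55.07,
                           atol=1e-12)

    def test_signed_requires_assignment(self):
        ffs = FormFactorSet(55.0, [1], [1.0])
        assert not ffs.assigned
        with pytest.raises(ValueError):
            _ = ffs.signed
        assert np.allclose(ffs.with_signs([-1]).signed, [-1.0])


class TestChainPeak:
    def test_noiseless_gaussian_recovered(self):
        q = np.linspace(0.9, 1.9, 3000)
        y = 30.0 + _gauss(q, 1.49, 0.05, 400.0)
        q_T, sigma, area = chain_peak(IntensityCurve(Axis.IN_PLANE, q, y))
        assert q_T == pytest.approx(1.49, abs=1e-6)
        assert sigma == pytest.approx(0.05, rel=1e-4)
        assert area == pytest.approx(400.0 * 0.05 * SQRT2PI, rel=1e-4)

    def test_seeded_fixture_center(self, fixture_pack):
        from memdiff.io import read_curve

        outdir, manifest = fixture_pack
        curve = read_curve(outdir / "inplane_gel.txt", Axis.IN_PLANE)
        q_T, _, _ = chain_peak(curve)
        assert abs(q_T - manifest["files"]["inplane_gel.txt"]["chain_q"]) < 0.005

    def test_no_peak_rejected(self):
        q = np.linspace(0.9, 1.9, 500)
        with pytest.raises(ValueError, match="significant"):
            chain_peak(IntensityCurve(Axis.IN_PLANE, q, np.full_like(q, 30.0)))

    def test_window_coverage_required(self):
        q = np.linspace(1.2, 1.6, 200)
        with pytest.raises(ValueError, match="cover"):
            chain_peak(IntensityCurve(Axis.IN_PLANE, q, np.ones_like(q)))

    def test_wrong_axis_rejected(self):
        q = np.linspace(0.9, 1.9, 200)
        with pytest.raises(ValueError, match="in-plane"):
            chain_peak(IntensityCurve(Axis.OUT_OF_PLANE, q, np.ones_like(q)))
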