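"""Peak detection, integration, calibration and quantitation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hopchem import catalog as cat
from hopchem.catalog import default_catalog, entries_for
from hopchem.chromatography import (
    CONE_EXTRACTION,
    CalibrationCurve,
    Chromatogram,
    ExtractionRecord,
    FLAG_BELOW_LOWEST,
    Ice3Composition,
    assign_compounds,
    detect_peaks,
    fit_calibration,
    integrate_peak,
    quantify,
    quantify_bitter_acids,
)
from hopchem.errors import (
    CurveError,
    DegenerateDesignError,
    InputError,
    RangeError,
    StandardMixtureError,
)
from hopchem.synthetic_data import (
    generate_calibration_series,
    simulate_chromatogram,
    simulate_trace,
)


def gaussian_trace(apexes, areas, sigma=0.01, baseline=0.0, duration=8.0,
                   points_per_min=1200):
    t = np.linspace(0.0, duration, int(duration * points_per_min) + 1)
    y = np.full_like(t, baseline)
    for apex, area in zip(apexes, areas):
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - apex) / sigma) ** 2)
    return Chromatogram(370, t, y)


class TestChromatogramValidation:
    def test_rejects_decreasing_time(self):
        with pytest.raises(InputError):
            Chromatogram(370, [0.0, 2.0, 1.0], [0.0, 0.0, 0.0])

    def test_rejects_non_finite(self):
        with pytest.raises(InputError):
            Chromatogram(370, [0.0, 1.0], [0.0, np.inf])

    def test_rejects_single_sample(self):
        with pytest.raises(InputError):
            Chromatogram(370, [0.0], [0.0])

    def test_text_round_trip(self, tmp_path):
        chrom = gaussian_trace([2.0], [5.0], baseline=1.0, duration=4.0)
        chrom.metadata["sample"] = "demo"
        path = tmp_path / "trace.txt"
        chrom.to_file(path)
        back = Chromatogram.from_file(path)
        assert back.channel_nm == 370
        assert back.metadata["sample"] == "demo"
        # stored precision is 6 decimal places
        assert np.allclose(back.time_min, chrom.time_min, atol=5e-7)
        assert np.allclose(back.absorbance_mau, chrom.absorbance_mau, atol=5e-7)


class TestDetectPeaks:
    def test_flat_trace_yields_no_peaks(self):
        t = np.linspace(0, 8, 1000)
        chrom = Chromatogram(370, t, np.full_like(t, 3.0))
        assert detect_peaks(chrom) == []

    def test_two_resolved_gaussians(self):
        """Two noiseless peaks > 6 widths apart: apexes found within one
        sampling interval."""
        chrom = gaussian_trace([2.0, 2.1], [10.0, 12.0])
        peaks = detect_peaks(chrom)
        assert len(peaks) == 2
        dt = chrom.time_min[1] - chrom.time_min[0]
        assert abs(peaks[0].apex_time - 2.0) <= dt
        assert abs(peaks[1].apex_time - 2.1) <= dt
        assert peaks[0].apex_time < peaks[1].apex_time

    def test_windows_are_disjoint(self):
        chrom = gaussian_trace([2.0, 2.2, 3.0], [10.0, 4.0, 7.0])
        peaks = detect_peaks(chrom)
        for a, b in zip(peaks[:-1], peaks[1:]):
            assert a.window[1] <= b.window[0] + 1e-12

    def test_lupuloides_cone_trace_four_prenylchalcones(self, default_panel,
                                                        catalog):
        """A lupuloides cone at 370 nm shows DXH, XGA, XHU and MXH."""
        truth = next(t for t in default_panel
                     if t.subspecies_label == "lupuloides")
        chrom = simulate_chromatogram(truth, "cone",
                                      cat.CHANNEL_PRENYLCHALCONES,
                                      noise_sd=0.0)
        entries = entries_for(catalog, "cone", cat.CHANNEL_PRENYLCHALCONES)
        peaks = assign_compounds(detect_peaks(chrom), entries)
        assigned = {p.compound_id for p in peaks if p.compound_id}
        assert assigned == {cat.DXH, cat.XGA, cat.XHU, cat.MXH}

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            detect_peaks(Chromatogram(370, [0.0, 1.0], [0.0, 0.0]))


class TestIntegratePeak:
    def test_zero_signal_integrates_to_zero(self):
        t = np.linspace(0, 8, 1000)
        chrom = Chromatogram(370, t, np.zeros_like(t))
        assert integrate_peak(chrom, (1.0, 3.0), baseline="zero") == 0.0

    def test_unit_area_gaussian(self):
        chrom = gaussian_trace([4.0], [1.0])
        area = integrate_peak(chrom, (4.0 - 0.06, 4.0 + 0.06), baseline="zero")
        assert area == pytest.approx(1.0, abs=5e-3)

    def test_constant_baseline_removed_by_linear_endpoints(self):
        free = gaussian_trace([4.0], [1.0], baseline=0.0)
        offset = gaussian_trace([4.0], [1.0], baseline=7.5)
        window = (4.0 - 0.08, 4.0 + 0.08)
        a0 = integrate_peak(free, window, baseline="zero")
        a1 = integrate_peak(offset, window, baseline="linear_endpoints")
        assert a1 == pytest.approx(a0, rel=1e-2)

    def test_agrees_with_fine_riemann_oracle(self):
        """Trapezoid vs brute-force fine-grid Riemann sum on random peaks."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            apex = rng.uniform(1.0, 7.0)
            area = rng.uniform(0.5, 200.0)
            sigma = rng.uniform(0.008, 0.02)
            chrom = gaussian_trace([apex], [area], sigma=sigma)
            window = (apex - 6 * sigma, apex + 6 * sigma)
            measured = integrate_peak(chrom, window, baseline="zero")
            # Riemann midpoint sum on a 100x finer grid
            tt = np.arange(window[0], window[1], 1 / 120000)
            yy = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((tt + 1 / 240000 - apex) / sigma) ** 2)
            oracle = float(np.sum(yy) / 120000)
            assert measured == pytest.approx(oracle, rel=1e-3)

    def test_empty_window_rejected(self):
        chrom = gaussian_trace([4.0], [1.0])
        with pytest.raises(InputError):
            integrate_peak(chrom, (5.0, 5.0))
        with pytest.raises(InputError):
            integrate_peak(chrom, (7.9, 9.5))


class TestFitCalibration:
    def test_perfect_line(self):
        points = [(c, 100.0 * c) for c in (0.001, 0.01, 0.1, 0.5)]
        curve = fit_calibration(points, "XHU")
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.valid_range == (0.001, 0.5)

    def test_three_point_closed_form(self):
        # OLS through (0,1), (1,2), (2,3): slope 1, intercept 1, r^2 = 1
        curve = fit_calibration([(0, 1), (1, 2), (2, 3)], "demo")
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_default_synthetic_series_r_squared(self):
        points = generate_calibration_series(cat.XHU, seed=0)
        curve = fit_calibration(points, cat.XHU)
        assert curve.r_squared > 0.999

    def test_refit_on_own_predictions_is_idempotent(self):
        points = generate_calibration_series(cat.Q_RUT, seed=1)
        curve = fit_calibration(points, cat.Q_RUT)
        predicted = [(c, curve.slope * c + curve.intercept) for c, _ in points]
        refit = fit_calibration(predicted, cat.Q_RUT)
        assert refit.slope == pytest.approx(curve.slope, rel=1e-12)
        assert refit.intercept == pytest.approx(curve.intercept, abs=1e-9)
        assert refit.r_squared == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_calibration([(0.1, 10.0), (0.1, 11.0)], "XHU")


class TestQuantify:
    CURVE = CalibrationCurve("XHU", slope=100.0, intercept=0.0,
                             r_squared=1.0, valid_range=(0.001, 0.5))

    def test_arithmetic_oracle(self):
        extraction = ExtractionRecord(500.0, 50.0, 1.0)
        result = quantify(10.0, self.CURVE, extraction)
        assert result.concentration_mg_ml == pytest.approx(0.1)
        assert result.percent_dw == pytest.approx(1.0)
        assert result.flags == ()

    def test_area_equal_to_intercept_gives_zero(self):
        curve = CalibrationCurve("XHU", 100.0, 5.0, 1.0, (0.001, 0.5))
        result = quantify(5.0, curve, CONE_EXTRACTION)
        assert result.percent_dw == 0.0

    def test_below_lowest_calibrant_flagged_not_censored(self):
        result = quantify(0.05, self.CURVE, CONE_EXTRACTION)
        assert FLAG_BELOW_LOWEST in result.flags
        assert result.percent_dw > 0.0

    def test_above_range_raises_advising_dilution(self):
        with pytest.raises(RangeError, match="dilute"):
            quantify(100.0, self.CURVE, CONE_EXTRACTION)

    def test_non_positive_slope_rejected(self):
        bad = CalibrationCurve("XHU", -1.0, 0.0, 1.0, (0.001, 0.5))
        with pytest.raises(CurveError):
            quantify(1.0, bad, CONE_EXTRACTION)

    @given(st.floats(0.0, 30.0), st.floats(1.1, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_in_area(self, area, k):
        """Doubling (area - intercept) doubles % dw (within range)."""
        curve = CalibrationCurve("XHU", 100.0, 2.0, 1.0, (0.001, 1.0))
        base = quantify(curve.intercept + area, curve, CONE_EXTRACTION)
        scaled = quantify(curve.intercept + k * area, curve, CONE_EXTRACTION)
        assert scaled.percent_dw == pytest.approx(k * base.percent_dw, rel=1e-9,
                                                  abs=1e-12)


class TestQuantifyBitterAcids:
    def test_ice3_identity_sample(self):
        """Sample areas equal to the 1 mg/ml ICE-3 standard's: cohumulone
        reads 1.388 % dw when 1 mg/ml corresponds to 10 % dw."""
        ice3 = Ice3Composition()
        rf = {"COH": 250.0, "nADH": 250.0, "COL": 200.0, "nADL": 200.0}
        std_areas = {cid: rf[cid] * ice3.analyte_concentration(cid)
                     for cid in rf}
        extraction = ExtractionRecord(500.0, 50.0)  # 1 mg/ml -> 10 % dw
        out = quantify_bitter_acids(std_areas, ice3, std_areas, extraction)
        assert out["COH"].percent_dw == pytest.approx(1.388)
        assert out["nADH"].percent_dw == pytest.approx(3.076)
        assert out["COL"].percent_dw == pytest.approx(1.344)
        assert out["nADL"].percent_dw == pytest.approx(1.084)

    def test_zero_areas_give_zero(self):
        ice3 = Ice3Composition()
        std_areas = {cid: 100.0 for cid in ("COH", "nADH", "COL", "nADL")}
        out = quantify_bitter_acids({}, ice3, std_areas, CONE_EXTRACTION)
        assert all(q.percent_dw == 0.0 for q in out.values())

    def test_recovers_generating_coh_proportion(self):
        """Noiseless synthetic cone with known COH proportion 0.41."""
        ice3 = Ice3Composition()
        rf = {"COH": 250.0, "nADH": 250.0, "COL": 200.0, "nADL": 200.0}
        std_areas = {cid: rf[cid] * ice3.analyte_concentration(cid)
                     for cid in rf}
        alpha_mg_ml = 0.6
        sample = {"COH": rf["COH"] * 0.41 * alpha_mg_ml,
                  "nADH": rf["nADH"] * 0.59 * alpha_mg_ml,
                  "COL": rf["COL"] * 0.3, "nADL": rf["nADL"] * 0.3}
        out = quantify_bitter_acids(sample, ice3, std_areas, CONE_EXTRACTION)
        prop = out["COH"].percent_dw / (out["COH"].percent_dw
                                        + out["nADH"].percent_dw)
        assert prop == pytest.approx(0.41, abs=0.01)

    def test_missing_standard_analyte_rejected(self):
        ice3 = Ice3Composition()
        with pytest.raises(StandardMixtureError):
            quantify_bitter_acids({}, ice3, {"COH": 1.0}, CONE_EXTRACTION)

    def test_ice3_default_composition(self):
        ice3 = Ice3Composition()
        assert ice3.fractions == {"COH": 0.1388, "nADH": 0.3076,
                                  "COL": 0.1344, "nADL": 0.1084}
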