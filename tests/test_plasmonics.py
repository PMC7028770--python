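"""LSPR peak detection, aggregation index, AuNP sizing and concentration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conan_assay.errors import (
    SpectrumError,
    UndefinedAIError,
    WavelengthMismatchError,
)
from conan_assay.plasmonics import (
    AuNPBatch,
    aggregation_index,
    ai_ratio,
    dilution_to_working,
    estimate_aunp_concentration,
    estimate_aunp_diameter,
    find_lspr_peak,
    qc_aunp_batch,
    with_ai_ratio,
)
from conan_assay.spectra import Spectrum
from tests.conftest import GRID, flat_spectrum, gaussian_spectrum


class TestFindLsprPeak:
    def test_finds_canonical_519_nm_band(self):
        peak = find_lspr_peak(gaussian_spectrum(center=519.0))
        assert peak.wavelength_nm == 519.0
        assert peak.absorbance == pytest.approx(1.0)
        assert peak.flags == ()

    def test_flat_spectrum_flags_leftmost_point(self):
        peak = find_lspr_peak(flat_spectrum(0.3))
        assert peak.wavelength_nm == 500.0
        assert "no_distinct_peak" in peak.flags

    def test_secondary_band_outside_window_warns(self):
        a = (
            np.exp(-((GRID - 519.0) ** 2) / (2 * 30.0**2))
            + 0.7 * np.exp(-((GRID - 700.0) ** 2) / (2 * 30.0**2))
        )
        peak = find_lspr_peak(Spectrum(GRID.copy(), a, "W"))
        assert peak.wavelength_nm == 519.0
        assert peak.absorbance == pytest.approx(1.0, rel=1e-3)
        assert "secondary_peak_outside_window" in peak.flags

    def test_window_not_covered_is_an_error(self):
        s = Spectrum(np.arange(600.0, 901.0), np.ones(301), "W")
        from conan_assay.errors import PeakDetectionError

        with pytest.raises(PeakDetectionError):
            find_lspr_peak(s)


class TestAggregationIndex:
    def test_flat_spectrum_gives_exactly_half(self):
        res = aggregation_index(flat_spectrum(0.8), 519.0)
        assert res.ai == 0.5

    def test_simple_arithmetic_case(self):
        # piecewise values A(519)=1, A(650)=A(850)=0.25 via interpolation nodes
        w = np.array([400.0, 519.0, 650.0, 850.0, 900.0])
        a = np.array([1.0, 1.0, 0.25, 0.25, 0.25])
        res = aggregation_index(Spectrum(w, a, "W"), 519.0)
        assert res.ai == pytest.approx(2.0)

    def test_gaussian_band_matches_closed_form(self):
        """Direct evaluation of the Gaussian at 519/650/850 nm as oracle."""
        res = aggregation_index(gaussian_spectrum(519.0, 30.0, 1.0), 519.0)
        oracle = 1.0 / (
            math.exp(-((650.0 - 519.0) ** 2) / (2 * 30.0**2))
            + math.exp(-((850.0 - 519.0) ** 2) / (2 * 30.0**2))
        )
        assert res.ai == pytest.approx(oracle, rel=1e-12)
        assert res.red2_wavelength_nm == 850.0

    def test_red2_falls_back_when_850_not_covered(self):
        grid = np.arange(400.0, 801.0, 1.0)
        res = aggregation_index(gaussian_spectrum(grid=grid, baseline=0.1), 519.0)
        assert res.red2_wavelength_nm == 800.0

    def test_nonpositive_denominator_is_undefined(self):
        w = np.array([400.0, 519.0, 650.0, 850.0, 900.0])
        a = np.array([1.0, 1.0, -0.1, 0.05, 0.0])
        with pytest.raises(UndefinedAIError):
            aggregation_index(Spectrum(w, a, "W"), 519.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        """AI is a ratio of absorbances: scaling the spectrum cannot move it."""
        base = gaussian_spectrum(baseline=0.05)
        scaled = Spectrum(GRID.copy(), k * base.absorbances_au, "W")
        a = aggregation_index(base, 519.0).ai
        b = aggregation_index(scaled, 519.0).ai
        assert b == pytest.approx(a, rel=1e-9)


class TestAiRatio:
    def test_self_ratio_is_exactly_100(self):
        res = aggregation_index(gaussian_spectrum(baseline=0.05), 519.0)
        assert ai_ratio(res, res) == 100.0

    def test_forty_five_percent_sample(self):
        norm = aggregation_index(gaussian_spectrum(baseline=0.05), 519.0)
        sample = type(norm)(**{**norm.__dict__, "ai": 0.45 * norm.ai})
        assert ai_ratio(sample, norm) == pytest.approx(45.0)

    def test_zero_ai_gives_zero_percent(self):
        norm = aggregation_index(gaussian_spectrum(baseline=0.05), 519.0)
        sample = type(norm)(**{**norm.__dict__, "ai": 0.0})
        assert ai_ratio(sample, norm) == 0.0

    def test_mismatched_wavelength_sets_hard_error(self):
        norm = aggregation_index(gaussian_spectrum(baseline=0.05), 519.0)
        other = aggregation_index(
            gaussian_spectrum(baseline=0.05), 519.0, (650.0, 800.0)
        )
        with pytest.raises(WavelengthMismatchError):
            ai_ratio(other, norm)

    def test_with_ai_ratio_attaches_percentage(self):
        norm = aggregation_index(gaussian_spectrum(baseline=0.05), 519.0)
        assert with_ai_ratio(norm, norm).ai_ratio_percent == 100.0


def _batch_spectrum(width: float = 70.6) -> Spectrum:
    # wider band than the aggregation surrogate: A_spr/A450 in the range the
    # UV-Vis sizing relations expect for ~14 nm citrate spheres
    return gaussian_spectrum(center=519.0, width=width, height=1.0)


class TestHaissEstimates:
    def test_exponent_zero_degenerate_case(self):
        # force A_spr/A450 = B2/B1 so the exponent vanishes and d = 1 nm
        w = np.array([400.0, 450.0, 519.0, 650.0, 850.0, 900.0])
        a = np.array([3.0, 3.0, 2.2, 0.1, 0.1, 0.1])
        d = estimate_aunp_diameter(Spectrum(w, a, "W"))
        assert d == pytest.approx(1.0)

    def test_ratio_1p7_gives_18_nm(self):
        w = np.array([400.0, 450.0, 519.0, 650.0, 850.0, 900.0])
        a = np.array([1.0, 1.0, 1.7, 0.1, 0.1, 0.1])
        d = estimate_aunp_diameter(Spectrum(w, a, "W"))
        assert d == pytest.approx(math.exp(3.00 * 1.70 - 2.20), rel=1e-12)
        assert d == pytest.approx(18.17, abs=0.01)

    def test_synthetic_batch_sizes_near_14_nm(self):
        d = estimate_aunp_diameter(_batch_spectrum())
        assert d == pytest.approx(14.0, abs=0.5)

    def test_concentration_against_spreadsheet_evaluation(self):
        """Independent step-by-step evaluation of the number-density formula."""
        w = np.array([400.0, 450.0, 519.0, 650.0, 850.0, 900.0])
        a = np.array([0.5, 0.5, 0.9, 0.1, 0.1, 0.1])
        s = Spectrum(w, a, "W")
        got = estimate_aunp_concentration(s, 14.0, path_length_cm=1.0)
        shape = -0.295 + 1.36 * math.exp(-(((14.0 - 96.8) / 78.2) ** 2))
        n_per_ml = 0.5 * 1e14 / (14.0**2 * shape)
        oracle_nM = n_per_ml * 1000.0 / 6.02214076e23 * 1e9
        assert got == pytest.approx(oracle_nM, rel=1e-12)

    def test_concentration_linear_in_a450_and_inverse_in_path(self):
        s1 = _batch_spectrum()
        s2 = Spectrum(GRID.copy(), 2 * s1.absorbances_au, "W")
        c1 = estimate_aunp_concentration(s1, 14.0, 0.3)
        assert estimate_aunp_concentration(s2, 14.0, 0.3) == pytest.approx(2 * c1)
        assert estimate_aunp_concentration(s1, 14.0, 0.15) == pytest.approx(2 * c1)

    def test_qc_pipeline_on_synthetic_batch(self):
        batch = qc_aunp_batch(_batch_spectrum(), batch_id="b1")
        assert batch.lspr_wavelength_nm == 519.0
        assert 10.0 < batch.diameter_nm < 20.0
        assert batch.concentration_nM > 6.0
        assert batch.flags == ()


class TestDilutionToWorking:
    @pytest.mark.parametrize(
        "stock,expected", [(18.2, 18.2 / 6.0), (6.0, 1.0), (12.0, 2.0)]
    )
    def test_factors(self, stock, expected):
        batch = AuNPBatch(519.0, 14.0, stock)
        assert dilution_to_working(batch) == pytest.approx(expected)

    def test_too_dilute_batch_rejected(self):
        with pytest.raises(ValueError, match="more dilute"):
            dilution_to_working(AuNPBatch(519.0, 14.0, 3.0))
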