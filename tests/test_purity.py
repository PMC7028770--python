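"""Reference points and dilution-series purity grading."""

import pytest

from conan_assay import pipeline
from conan_assay.config import RunConfig
from conan_assay.errors import PurityError
from conan_assay.purity import (
    DilutionSeries,
    PurityConfig,
    SeriesPoint,
    Verdict,
    build_references,
    classify_series,
    sap_statement,
)
from conan_assay.spectra import LayoutEntry, PlateLayout, PlateSpectra, Role, subtract_blank
from conan_assay.synth import Scenario, ScenarioKind, generate_plate


def _refs(int_ref_target: float = 47.0):
    gen = generate_plate(
        Scenario(kind=ScenarioKind.CALIBRATION, seed=2,
                 int_ref_ai_ratio_percent=int_ref_target),
        with_noise=False,
    )
    plate = subtract_blank(gen.plate)
    return build_references(plate)


def _series(points, sample_id="S"):
    return DilutionSeries(
        sample_id=sample_id,
        points=tuple(SeriesPoint(d, r) for d, r in points),
    )


class TestBuildReferences:
    def test_intref_at_47_percent_no_warnings(self):
        refs = _refs(47.0)
        assert refs.norm_ref.ai_ratio_percent == 100.0
        assert refs.int_ref_ai_ratio_percent == pytest.approx(47.0, abs=1e-6)
        assert refs.warnings == ()

    def test_intref_outside_band_warns(self):
        refs = _refs(62.0)
        assert any("outside the expected band" in w for w in refs.warnings)

    def test_missing_intref_group_is_an_error(self, clean_calibration_plate):
        plate = subtract_blank(clean_calibration_plate.plate)
        entries = tuple(e for e in plate.layout.entries if e.role is not Role.INT_REF)
        import pytest as _pt

        with _pt.raises(Exception):
            # layout itself refuses to exist without an intREF group
            PlateLayout(entries=entries)

    def test_uncorrected_plate_rejected(self, clean_calibration_plate):
        with pytest.raises(PurityError, match="blank-corrected"):
            build_references(clean_calibration_plate.plate)


@pytest.fixture(scope="module")
def refs47():
    return _refs(47.0)


class TestClassifySeries:
    def test_case1_concentrated_decays_below_lod(self, refs47):
        v = classify_series(_series([(1, 70.0), (10, 35.0), (100, 15.0)]), refs47)
        assert v.verdict is Verdict.CASE1_PURE_CONCENTRATED
        assert v.quantification_point == SeriesPoint(100, 15.0)
        assert v.sap_below_lod

    def test_case3_contaminated_plateau(self, refs47):
        v = classify_series(_series([(10, 65.0), (30, 66.0), (100, 64.0)]), refs47)
        assert v.verdict is Verdict.CASE3_CONTAMINATED
        assert v.quantification_point is None
        assert not v.sap_below_lod

    def test_no_ev_flat_at_intref(self, refs47):
        v = classify_series(_series([(10, 49.0), (100, 47.0)]), refs47)
        assert v.verdict is Verdict.NO_EV
        assert v.quantification_point is None

    def test_case2_pure_between_intref_and_lod(self, refs47):
        v = classify_series(_series([(10, 40.0), (30, 25.0), (100, 12.0)]), refs47)
        assert v.verdict is Verdict.CASE2_PURE
        assert v.quantification_point == SeriesPoint(100, 12.0)

    def test_quantification_prefers_least_diluted_qualifying_point(self, refs47):
        v = classify_series(_series([(1, 70.0), (10, 18.0), (100, 8.0)]), refs47)
        assert v.verdict is Verdict.CASE1_PURE_CONCENTRATED
        assert v.quantification_point == SeriesPoint(10, 18.0)

    def test_all_points_below_lod_still_case2_with_note(self, refs47):
        v = classify_series(_series([(10, 12.0), (100, 8.0)]), refs47)
        assert v.verdict is Verdict.CASE2_PURE
        assert any("verify_ev_presence" in e for e in v.evidence)

    def test_decreasing_but_never_reaching_lod_says_dilute_further(self, refs47):
        v = classify_series(_series([(10, 80.0), (100, 30.0)]), refs47)
        assert v.verdict is Verdict.INCONCLUSIVE
        assert "dilute_further" in v.evidence

    def test_overdiluted_rise_beyond_500(self, refs47):
        v = classify_series(_series([(10, 32.0), (300, 22.0), (1000, 30.0)]), refs47)
        assert v.verdict is Verdict.OVERDILUTED
        assert any(e.startswith("overdiluted") for e in v.evidence)
        assert v.quantification_point is None

    def test_truncated_series_can_still_be_pure(self, refs47):
        """A clean decay below the LOD before the over-diluted tail keeps its grade."""
        v = classify_series(
            _series([(10, 70.0), (100, 15.0), (1000, 28.0)]), refs47
        )
        assert v.verdict is Verdict.CASE1_PURE_CONCENTRATED
        assert any(e.startswith("overdiluted") for e in v.evidence)
        assert v.quantification_point == SeriesPoint(100, 15.0)

    def test_quantification_iff_pure_verdict(self, refs47):
        """CASE1/CASE2 always carry a quantification point; others never do."""
        cases = [
            [(1, 70.0), (10, 35.0), (100, 15.0)],
            [(10, 40.0), (30, 25.0), (100, 12.0)],
            [(10, 65.0), (30, 66.0), (100, 64.0)],
            [(10, 49.0), (100, 47.0)],
            [(10, 32.0), (300, 22.0), (1000, 30.0)],
            [(10, 80.0), (100, 30.0)],
        ]
        for pts in cases:
            v = classify_series(_series(pts), refs47)
            has_point = v.quantification_point is not None
            assert has_point == (
                v.verdict in (Verdict.CASE1_PURE_CONCENTRATED, Verdict.CASE2_PURE)
            )

    def test_intermediate_consistent_dilution_does_not_change_verdict(self, refs47):
        base = classify_series(_series([(1, 70.0), (100, 15.0)]), refs47)
        more = classify_series(_series([(1, 70.0), (10, 40.0), (100, 15.0)]), refs47)
        assert base.verdict is more.verdict is Verdict.CASE1_PURE_CONCENTRATED

    def test_too_short_series_rejected(self, refs47):
        with pytest.raises(PurityError, match=">= 2"):
            classify_series(_series([(10, 30.0)]), refs47)

    def test_calibration_window_restricts_quantification(self, refs47):
        cfg = PurityConfig(calibration_ai_range_percent=(10.0, 50.0))
        v = classify_series(
            _series([(10, 40.0), (30, 18.0), (100, 4.0)]), refs47, cfg
        )
        assert v.verdict is Verdict.CASE2_PURE
        # the 4% point is below the invertible window; 18% qualifies
        assert v.quantification_point == SeriesPoint(30, 18.0)


class TestSapStatement:
    def test_below_lod_certifies_sap_bound(self, refs47):
        v = classify_series(_series([(1, 70.0), (10, 35.0), (100, 15.0)]), refs47)
        below, text = sap_statement(v, refs47)
        assert below and "0.05" in text

    def test_lod_threshold_is_inclusive(self, refs47):
        v = classify_series(_series([(10, 45.0), (100, 20.0)]), refs47)
        below, _ = sap_statement(v, refs47)
        assert below

    def test_contaminated_sample_not_certified(self, refs47):
        v = classify_series(_series([(10, 65.0), (30, 66.0), (100, 64.0)]), refs47)
        below, text = sap_statement(v, refs47)
        assert not below and "not established" in text


class TestScenarioLabelAgreement:
    """Noise-free generated scenarios classify back to their generating label."""

    @pytest.mark.parametrize(
        "kind,expected",
        [
            (ScenarioKind.PURE_CONCENTRATED, Verdict.CASE1_PURE_CONCENTRATED),
            (ScenarioKind.PURE, Verdict.CASE2_PURE),
            (ScenarioKind.CONTAMINATED, Verdict.CASE3_CONTAMINATED),
            (ScenarioKind.NO_EV, Verdict.NO_EV),
            (ScenarioKind.OVERDILUTED, Verdict.OVERDILUTED),
        ],
    )
    def test_label_recovered(self, kind, expected):
        gen = generate_plate(Scenario(kind=kind, seed=4), with_noise=False)
        cfg = RunConfig()
        run = pipeline.calibrate_plate(gen.plate, cfg)
        grade = pipeline.grade_plate(gen.plate, run.model, cfg)
        assert grade.verdicts["S1"].verdict is expected
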