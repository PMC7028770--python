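"""End-to-end orchestration: plate -> calibration -> verdicts -> titration.

Thin composition layer over the spectra / plasmonics / calibration /
purity / titration modules; the command-line interface and the test
benches both drive the pipeline through these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import plasmonics, purity as purity_mod
from .calibration import (
    CalibrationModel,
    StandardPoint,
    check_batch,
    fit_calibration,
    invert_calibration,
)
from .config import RunConfig
from .errors import CalibrationError, PurityError
from .plasmonics import AggregationResult
from .purity import (
    DilutionSeries,
    PurityConfig,
    PurityVerdict,
    ReferenceSet,
    SeriesPoint,
    build_references,
    classify_series,
)
from .spectra import PlateSpectra, Role, Spectrum, subtract_blank, summarize_values
from .titration import (
    TitrationResult,
    VesicleGeometry,
    back_scale_concentration,
    titrate_sample,
)


def ensure_blank_corrected(plate: PlateSpectra) -> PlateSpectra:
    """Blank-correct a plate unless already done."""
    return plate if plate.blank_corrected else subtract_blank(plate)


def well_ai_results(
    plate: PlateSpectra, refs: ReferenceSet, roles: tuple[Role, ...] = (Role.STANDARD, Role.SAMPLE)
) -> dict[str, AggregationResult]:
    """Per-well AI and AI ratio at the plate's fixed wavelength set."""
    out: dict[str, AggregationResult] = {}
    for e in plate.layout.entries:
        if e.role not in roles:
            continue
        res = plasmonics.aggregation_index(
            plate.spectra[e.well],
            refs.lspr_wavelength_nm,
            (plasmonics.RED1_NM, refs.red2_wavelength_nm),
        )
        out[e.well] = plasmonics.with_ai_ratio(res, refs.norm_ref)
    return out


def standard_points(
    plate: PlateSpectra, refs: ReferenceSet, statistic_level: str = "index"
) -> list[StandardPoint]:
    """Replicate-aggregated AI ratio of every standard concentration.

    Default aggregation is at the index level (AI per well, then mean and
    sd per replicate group); ``statistic_level="spectrum"`` averages the
    replicate spectra pointwise before computing a single AI.
    """
    groups: dict[float, list[str]] = {}
    for e in plate.layout.by_role(Role.STANDARD):
        assert e.concentration_mg_per_ml is not None
        groups.setdefault(e.concentration_mg_per_ml, []).append(e.well)
    pts = []
    for conc in sorted(groups, reverse=True):
        ratio, sd, n = _group_ai_ratio(plate, refs, groups[conc], statistic_level)
        pts.append(StandardPoint(conc, ratio, sd, n))
    return pts


def _group_ai_ratio(
    plate: PlateSpectra, refs: ReferenceSet, wells: list[str], statistic_level: str
) -> tuple[float, float, int]:
    red = (plasmonics.RED1_NM, refs.red2_wavelength_nm)
    if statistic_level == "spectrum":
        mean = Spectrum(
            wavelengths_nm=plate.wavelengths_nm,
            absorbances_au=np.mean(
                [plate.spectra[w].absorbances_au for w in wells], axis=0
            ),
            well_id="+".join(wells),
        )
        res = plasmonics.aggregation_index(mean, refs.lspr_wavelength_nm, red)
        return plasmonics.ai_ratio(res, refs.norm_ref), 0.0, len(wells)
    results = [
        plasmonics.with_ai_ratio(
            plasmonics.aggregation_index(plate.spectra[w], refs.lspr_wavelength_nm, red),
            refs.norm_ref,
        )
        for w in wells
    ]
    stats = summarize_values([r.ai_ratio_percent for r in results])  # type: ignore[misc]
    return stats.mean, stats.sd, stats.n


@dataclass(frozen=True)
class CalibrationRun:
    model: CalibrationModel
    refs: ReferenceSet
    plate: PlateSpectra  # blank-corrected


def calibrate_plate(
    plate: PlateSpectra, config: RunConfig = RunConfig()
) -> CalibrationRun:
    """Build the calibration line from a standards plate."""
    plate = ensure_blank_corrected(plate)
    refs = build_references(plate, config.purity, config.red2, config.smooth_window)
    pts = standard_points(plate, refs, config.statistic_level)
    if not pts:
        raise CalibrationError("plate contains no STANDARD wells")
    model = fit_calibration(
        pts,
        red2_nm=refs.red2_wavelength_nm,
        batch_id=plate.layout.aunp_batch_id or "",
    )
    return CalibrationRun(model=model, refs=refs, plate=plate)


def sample_series(
    plate: PlateSpectra, refs: ReferenceSet, statistic_level: str = "index"
) -> dict[str, DilutionSeries]:
    """Per-sample dilution series of replicate-mean AI ratios."""
    by_sample: dict[str, dict[float, list[str]]] = {}
    for e in plate.layout.by_role(Role.SAMPLE):
        assert e.sample_id is not None and e.dilution_factor is not None
        by_sample.setdefault(e.sample_id, {}).setdefault(e.dilution_factor, []).append(e.well)
    out: dict[str, DilutionSeries] = {}
    for sid, dilutions in by_sample.items():
        points = []
        for d in sorted(dilutions):
            ratio, sd, n = _group_ai_ratio(plate, refs, dilutions[d], statistic_level)
            points.append(SeriesPoint(d, ratio, sd, n))
        out[sid] = DilutionSeries(sample_id=sid, points=tuple(points))
    return out


@dataclass(frozen=True)
class GradeRun:
    refs: ReferenceSet
    series: dict[str, DilutionSeries]
    verdicts: dict[str, PurityVerdict]
    plate: PlateSpectra


def grade_plate(
    plate: PlateSpectra,
    model: CalibrationModel | None = None,
    config: RunConfig = RunConfig(),
) -> GradeRun:
    """Grade every sample on a plate into the purity cases.

    When a calibration model is supplied, its AuNP batch must match the
    plate's declared batch, its red2 wavelength is used for the AI
    definition, and its AI-ratio window restricts quantification points.
    """
    red2: str | float = config.red2
    pur_cfg = config.purity
    if model is not None:
        check_batch(model, plate.layout.aunp_batch_id)
        red2 = model.red2_wavelength_nm
        if pur_cfg.calibration_ai_range_percent is None:
            pur_cfg = replace(
                pur_cfg, calibration_ai_range_percent=model.ai_ratio_range_percent
            )
    plate = ensure_blank_corrected(plate)
    refs = build_references(plate, pur_cfg, red2, config.smooth_window)
    series = sample_series(plate, refs, config.statistic_level)
    if not series:
        raise PurityError("plate contains no SAMPLE wells")
    verdicts = {sid: classify_series(s, refs, pur_cfg) for sid, s in series.items()}
    return GradeRun(refs=refs, series=series, verdicts=verdicts, plate=plate)


def quantify_sample(
    grade: GradeRun,
    model: CalibrationModel,
    sample_id: str,
    geometry: VesicleGeometry,
    config: RunConfig = RunConfig(),
) -> TitrationResult:
    """Titrate one graded sample (gatekeeper enforced downstream)."""
    verdict = grade.verdicts[sample_id]
    return titrate_sample(
        verdict,
        model,
        geometry,
        lipid_molar_mass_g_mol=config.popc_molar_mass_g_mol,
        assay_geometry_factor=config.assay_geometry_factor,
        plate_batch_id=grade.plate.layout.aunp_batch_id,
    )


def recover_sample_concentration(
    grade: GradeRun,
    model: CalibrationModel,
    sample_id: str,
    config: RunConfig = RunConfig(),
) -> float:
    """Recovered original lipid concentration [mg/ml] of a pure sample.

    Inversion of the calibration at the quantification point, back-scaled
    by the assay geometry factor and the pre-dilution — the concentration
    half of titration, without requiring a vesicle diameter.
    """
    verdict = grade.verdicts[sample_id]
    if verdict.quantification_point is None:
        raise PurityError(
            f"sample {sample_id!r} graded {verdict.verdict.value}: no quantification point"
        )
    point = verdict.quantification_point
    well_conc = invert_calibration(model, point.ai_ratio_percent)
    return back_scale_concentration(
        well_conc, point.dilution_factor, config.assay_geometry_factor
    )
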