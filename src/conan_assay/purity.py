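"""Reference points and purity grading of dilution series.

Three reference points anchor every plate:

* **blank** — water; subtracted from every spectrum (spectra module);
* **normREF** — dispersed AuNPs in water; its AI defines the 100 % AI
  ratio anchor;
* **intREF** — AuNPs plus PBS but no vesicles; its AI ratio (expected
  45–50 %) is the threshold below which a red shift is attributable to
  vesicle–particle interaction rather than buffer salt.

A sample is measured as a short dilution series (advised 1:10, 1:30,
1:100).  The trajectory of its AI ratio across dilutions separates four
situations:

* pure but concentrated — starts above the intREF, falls below the 20 %
  limit of detection (LOD) on dilution;
* pure — like the above but already at/below the intREF undiluted;
* contaminated — soluble exogenous proteins (SAPs) passivate the
  particles, so the AI ratio plateaus around 60–70 % regardless of
  dilution;
* no vesicles — the series sits at the intREF level and stays there.

An AI ratio <= 20 % additionally certifies SAP content below 0.05 ug/ul
(the assay's SAP LOD).  Only pure verdicts unlock titration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from . import plasmonics
from .errors import PurityError
from .plasmonics import AggregationResult
from .spectra import GroupStats, PlateSpectra, Role, Spectrum, summarize_values

#: AI ratio at/below which soluble-protein contamination is below the SAP LOD
LOD_AI_RATIO_PERCENT = 20.0
SAP_LOD_UG_PER_UL = 0.05
#: expected intREF AI-ratio band [%]
INT_REF_BAND_PERCENT = (45.0, 50.0)


@dataclass(frozen=True)
class PurityConfig:
    """Thresholds of the grading decision procedure.

    The protocol states its rules qualitatively ("stays constant",
    "similar to the intREF"); the numeric tolerances below are explicit
    choices of this implementation, echoed into every report:

    * ``flat_tol`` — a series whose spread is within this many percentage
      points counts as flat, and "similar to intREF" means within it of
      the intREF AI ratio.  The contaminated plateau spans ~10 points
      (60–70 %); 8 separates a plateau from genuine decay.
    * ``noise_tol`` — allowed uphill wiggle when testing that a series is
      non-increasing.
    * ``rise_tol`` — rise above the series minimum that, at dilutions
      beyond ``overdilution_factor``, marks over-dilution.
    """

    lod_ai_ratio_percent: float = LOD_AI_RATIO_PERCENT
    sap_lod_ug_per_ul: float = SAP_LOD_UG_PER_UL
    int_ref_band_percent: tuple[float, float] = INT_REF_BAND_PERCENT
    flat_tol: float = 8.0
    noise_tol: float = 5.0
    rise_tol: float = 5.0
    overdilution_factor: float = 500.0
    #: optional (lo, hi) AI-ratio window of the calibration in use; when set,
    #: a quantification point must also be invertible within it (plus grace)
    calibration_ai_range_percent: tuple[float, float] | None = None
    calibration_grace_percent: float = 2.0

    def to_dict(self) -> dict:
        return {
            "lod_ai_ratio_percent": self.lod_ai_ratio_percent,
            "sap_lod_ug_per_ul": self.sap_lod_ug_per_ul,
            "int_ref_band_percent": list(self.int_ref_band_percent),
            "flat_tol": self.flat_tol,
            "noise_tol": self.noise_tol,
            "rise_tol": self.rise_tol,
            "overdilution_factor": self.overdilution_factor,
            "calibration_ai_range_percent": (
                None if self.calibration_ai_range_percent is None
                else list(self.calibration_ai_range_percent)
            ),
            "calibration_grace_percent": self.calibration_grace_percent,
        }


@dataclass(frozen=True)
class ReferenceSet:
    """The plate's normREF / intREF anchors (replicate-group means)."""

    norm_ref: AggregationResult  # ai_ratio_percent == 100 by construction
    int_ref: AggregationResult
    norm_stats: GroupStats
    int_stats: GroupStats
    lod_ai_ratio_percent: float = LOD_AI_RATIO_PERCENT
    sap_lod_ug_per_ul: float = SAP_LOD_UG_PER_UL
    warnings: tuple[str, ...] = ()

    @property
    def lspr_wavelength_nm(self) -> float:
        return self.norm_ref.lspr_wavelength_nm

    @property
    def red2_wavelength_nm(self) -> float:
        return self.norm_ref.red2_wavelength_nm

    @property
    def int_ref_ai_ratio_percent(self) -> float:
        assert self.int_ref.ai_ratio_percent is not None
        return self.int_ref.ai_ratio_percent


def build_references(
    plate: PlateSpectra,
    config: PurityConfig = PurityConfig(),
    red2: float | str = "auto",
    smooth_window: int | None = None,
) -> ReferenceSet:
    """Compute the plate's reference anchors.

    The LSPR wavelength is detected once, on the pointwise-mean normREF
    spectrum (monodispersed particles; averaging suppresses single-well
    noise), and every other well on the plate is sampled at that fixed
    wavelength.  Per-well AIs of each reference group are averaged at the
    index level.

    Errors: plate not blank-corrected, missing reference group, intREF AI
    ratio >= 100 %.  An intREF outside the expected 45–50 % band attaches
    a warning but does not fail.
    """
    if not plate.blank_corrected:
        raise PurityError("build_references needs a blank-corrected plate")
    norm_wells = [e.well for e in plate.layout.by_role(Role.NORM_REF)]
    int_wells = [e.well for e in plate.layout.by_role(Role.INT_REF)]
    if not norm_wells:
        raise PurityError("missing normREF replicate group")
    if not int_wells:
        raise PurityError("missing intREF replicate group")

    norm_spectra = [plate.spectra[w] for w in norm_wells]
    mean_norm = Spectrum(
        wavelengths_nm=norm_spectra[0].wavelengths_nm,
        absorbances_au=np.mean([s.absorbances_au for s in norm_spectra], axis=0),
        well_id="normREF(mean)",
    )
    peak = plasmonics.find_lspr_peak(mean_norm, smooth_window=smooth_window)
    lspr = peak.wavelength_nm
    red2_nm = plasmonics.resolve_red2(mean_norm, red2)

    def group_result(wells: list[str], entity: str) -> tuple[AggregationResult, GroupStats]:
        results = [
            plasmonics.aggregation_index(
                plate.spectra[w], lspr, (plasmonics.RED1_NM, red2_nm)
            )
            for w in wells
        ]
        stats = summarize_values([r.ai for r in results])
        mean = AggregationResult(
            entity_id=entity,
            ai=stats.mean,
            lspr_wavelength_nm=lspr,
            abs_lspr=float(np.mean([r.abs_lspr for r in results])),
            abs_red1=float(np.mean([r.abs_red1 for r in results])),
            abs_red2=float(np.mean([r.abs_red2 for r in results])),
            red1_wavelength_nm=plasmonics.RED1_NM,
            red2_wavelength_nm=red2_nm,
            flags=stats.flags + peak.flags if entity == "normREF" else stats.flags,
        )
        return mean, stats

    norm_mean, norm_stats = group_result(norm_wells, "normREF")
    int_mean, int_stats = group_result(int_wells, "intREF")

    norm_mean = plasmonics.with_ai_ratio(norm_mean, norm_mean)  # 100 by construction
    int_mean = plasmonics.with_ai_ratio(int_mean, norm_mean)
    assert int_mean.ai_ratio_percent is not None
    if int_mean.ai_ratio_percent >= 100.0:
        raise PurityError(
            f"intREF AI ratio {int_mean.ai_ratio_percent:.1f}% >= 100% — the "
            "no-EV control cannot exceed the dispersed reference"
        )
    warnings_: list[str] = []
    lo, hi = config.int_ref_band_percent
    if not lo <= int_mean.ai_ratio_percent <= hi:
        warnings_.append(
            f"intREF AI ratio {int_mean.ai_ratio_percent:.1f}% outside the "
            f"expected band [{lo:g}, {hi:g}]%"
        )
    return ReferenceSet(
        norm_ref=norm_mean,
        int_ref=int_mean,
        norm_stats=norm_stats,
        int_stats=int_stats,
        lod_ai_ratio_percent=config.lod_ai_ratio_percent,
        sap_lod_ug_per_ul=config.sap_lod_ug_per_ul,
        warnings=tuple(warnings_),
    )


@dataclass(frozen=True)
class SeriesPoint:
    """One dilution of a sample: replicate-mean AI ratio."""

    dilution_factor: float
    ai_ratio_percent: float
    sd: float = 0.0
    n: int = 1


@dataclass(frozen=True)
class DilutionSeries:
    """A sample's AI ratios across its dilution points, least diluted first."""

    sample_id: str
    points: tuple[SeriesPoint, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise PurityError(f"sample {self.sample_id!r}: empty dilution series")
        factors = [p.dilution_factor for p in self.points]
        if any(f < 1 for f in factors):
            raise PurityError(f"sample {self.sample_id!r}: dilution factors must be >= 1")
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise PurityError(
                f"sample {self.sample_id!r}: dilution factors must be strictly increasing"
            )

    def ai_ratios(self) -> list[float]:
        return [p.ai_ratio_percent for p in self.points]


class Verdict(Enum):
    """Purity grade of a dilution series."""

    CASE1_PURE_CONCENTRATED = "CASE1_PURE_CONCENTRATED"
    CASE2_PURE = "CASE2_PURE"
    CASE3_CONTAMINATED = "CASE3_CONTAMINATED"
    NO_EV = "NO_EV"
    OVERDILUTED = "OVERDILUTED"
    INCONCLUSIVE = "INCONCLUSIVE"


#: verdicts that permit titration
PURE_VERDICTS = (Verdict.CASE1_PURE_CONCENTRATED, Verdict.CASE2_PURE)


@dataclass(frozen=True)
class PurityVerdict:
    """Outcome of grading one sample."""

    sample_id: str
    verdict: Verdict
    quantification_point: SeriesPoint | None
    evidence: tuple[str, ...]
    sap_below_lod: bool

    @property
    def allows_titration(self) -> bool:
        return self.verdict in PURE_VERDICTS and self.quantification_point is not None


def classify_series(
    series: DilutionSeries,
    refs: ReferenceSet,
    config: PurityConfig = PurityConfig(),
) -> PurityVerdict:
    """Grade a dilution series against the plate's reference points.

    Decision procedure (tolerances from ``config``):

    1. *Over-dilution screen.*  If the AI ratio attains a minimum and then
       rises by more than ``rise_tol`` at a dilution beyond
       ``overdilution_factor`` (the "homeopathic" regime where buffer
       effects dominate), the series is truncated at its minimum and
       flagged; one should stop diluting once the AI ratio is below the
       LOD anyway.
    2. *No vesicles*: every point within ``flat_tol`` of the intREF AI
       ratio and none at/below the LOD.
    3. *Contaminated*: flat series (spread <= ``flat_tol``) whose mean
       sits more than ``flat_tol`` above the intREF — the SAP plateau.
    4. *Pure*: non-increasing within ``noise_tol`` with a minimum at/below
       the LOD.  Pure-but-concentrated (CASE 1) when the least-diluted
       point is above the intREF, plain pure (CASE 2) otherwise.  The
       quantification point is the least-diluted point at/below the LOD
       that the calibration can invert (best signal-to-noise, smallest
       back-multiplication of error).
    5. Otherwise inconclusive, with machine-readable evidence codes
       (e.g. ``dilute_further`` when the series decays but never reaches
       the LOD).

    When the over-dilution screen fired and the truncated series is still
    not interpretable, the verdict is OVERDILUTED.
    """
    pts = list(series.points)
    if len(pts) < 2:
        raise PurityError(
            f"sample {series.sample_id!r}: need >= 2 dilution points to classify"
        )
    int_ref = refs.int_ref_ai_ratio_percent
    lod = config.lod_ai_ratio_percent
    evidence: list[str] = []

    ratios = [p.ai_ratio_percent for p in pts]
    sap_below_lod = min(ratios) <= lod

    # 1 — over-dilution screen
    overdiluted = False
    i_min = int(np.argmin(ratios))
    for j in range(i_min + 1, len(pts)):
        if (
            pts[j].dilution_factor > config.overdilution_factor
            and ratios[j] - ratios[i_min] > config.rise_tol
        ):
            overdiluted = True
            break
    if overdiluted:
        evidence.append(
            f"overdiluted_rise_beyond_1:{config.overdilution_factor:g}"
        )
        pts = pts[: i_min + 1]
        ratios = ratios[: i_min + 1]

    verdict: Verdict
    quant: SeriesPoint | None = None

    def in_calibration_window(ai: float) -> bool:
        if config.calibration_ai_range_percent is None:
            return True
        lo, hi = config.calibration_ai_range_percent
        g = config.calibration_grace_percent
        return (lo - g) <= ai <= (hi + g)

    if len(pts) < 2:
        verdict = Verdict.INCONCLUSIVE
        evidence.append("single_point_after_truncation")
    elif all(abs(r - int_ref) <= config.flat_tol for r in ratios) and min(ratios) > lod:
        verdict = Verdict.NO_EV
        evidence.append("flat_at_intref_level")
    elif (max(ratios) - min(ratios) <= config.flat_tol) and (
        float(np.mean(ratios)) > int_ref + config.flat_tol
    ):
        verdict = Verdict.CASE3_CONTAMINATED
        evidence.append("flat_plateau_above_intref")
    elif (
        all(b <= a + config.noise_tol for a, b in zip(ratios, ratios[1:]))
        and min(ratios) <= lod
    ):
        candidates = [
            p for p in pts
            if p.ai_ratio_percent <= lod and in_calibration_window(p.ai_ratio_percent)
        ]
        if candidates:
            quant = candidates[0]  # least diluted qualifying point
            if ratios[0] > int_ref:
                verdict = Verdict.CASE1_PURE_CONCENTRATED
                evidence.append("decays_from_above_intref_to_lod")
            else:
                verdict = Verdict.CASE2_PURE
                evidence.append("at_or_below_intref_reaching_lod")
            if all(r <= lod for r in series.ai_ratios()):
                evidence.append("all_points_below_lod_verify_ev_presence_orthogonally")
        else:
            verdict = Verdict.INCONCLUSIVE
            evidence.append("below_lod_but_outside_calibration_window")
    else:
        verdict = Verdict.INCONCLUSIVE
        if (
            all(b <= a + config.noise_tol for a, b in zip(ratios, ratios[1:]))
            and min(ratios) > lod
        ):
            evidence.append("dilute_further")
        else:
            evidence.append("pattern_unrecognized")

    if overdiluted and verdict in (Verdict.INCONCLUSIVE, Verdict.NO_EV):
        verdict = Verdict.OVERDILUTED
        quant = None

    return PurityVerdict(
        sample_id=series.sample_id,
        verdict=verdict,
        quantification_point=quant,
        evidence=tuple(evidence),
        sap_below_lod=sap_below_lod,
    )


def sap_statement(
    verdict: PurityVerdict, refs: ReferenceSet | None = None
) -> tuple[bool, str]:
    """Human-readable soluble-protein statement for a graded sample.

    The assay only provides a detection *bound*: an AI ratio at/below the
    LOD certifies SAP below 0.05 ug/ul; above it, the SAP content is
    simply not established.
    """
    lod_ug = refs.sap_lod_ug_per_ul if refs is not None else SAP_LOD_UG_PER_UL
    if verdict.sap_below_lod:
        return True, f"SAP < {lod_ug:g} μg/μl"
    return False, "SAP content not established (no point at/below the AI-ratio LOD)"
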