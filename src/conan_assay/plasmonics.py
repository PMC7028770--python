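"""LSPR peak detection, aggregation index (AI) and AuNP batch QC.

Citrate-capped spherical gold nanoparticles (~15 nm) show a sharp
localized surface plasmon resonance (LSPR) extinction band near 519 nm.
Clustering of the particles — here, onto vesicle membranes — red-shifts
and broadens the band, turning the solution from red to blue.  The
aggregation index condenses a spectrum into one number:

    AI = Abs(LSPR) / (Abs(650 nm) + Abs(850 nm))

where Abs(LSPR) is sampled at the LSPR wavelength of the *monodispersed*
reference particles.  Monodispersed batches give a high AI; aggregated
wells a low one.  Expressed against the dispersed-AuNP reference:

    AI ratio = 100 * AI_sample / AI_AuNPs   [%]

so 100 % means fully dispersed.  When the reader cannot reach 850 nm the
second red term may be substituted by 800 or 780 nm, provided the same
set is used for calibration and samples alike (enforced here).

The module also estimates batch diameter and molar concentration from the
spectrum using the empirical UV-Vis relations of Haiss and co-workers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    PeakDetectionError,
    SpectrumError,
    UndefinedAIError,
    WavelengthMismatchError,
)
from .spectra import LOW_SIGNAL_AU, LSPR_WINDOW_NM, Spectrum

#: red-shift wavelengths: fixed first term, fallback order for the second
RED1_NM = 650.0
RED2_FALLBACK_NM = (850.0, 800.0, 780.0)

# Empirical constants of the Haiss et al. UV-Vis sizing relations for
# citrate gold spheres (they originate from that reference, not from the
# assay protocol itself).  d = exp(B1 * A_spr/A_450 - B2); the number
# density uses the C* constants below.
HAISS_B1 = 3.00
HAISS_B2 = 2.20
HAISS_C1 = -0.295
HAISS_C2 = 1.36
HAISS_C3 = 96.8
HAISS_C4 = 78.2

#: effective optical path of ~100 ul in a flat-bottom 96-well plate [cm]
DEFAULT_PATH_LENGTH_CM = 0.30

AVOGADRO = 6.02214076e23  # 1/mol

#: Haiss sizing relations are parameterized for diameters in this range [nm]
HAISS_DIAMETER_RANGE_NM = (3.0, 120.0)
#: secondary peaks above this fraction of the main peak flag a bad batch
SECONDARY_PEAK_FRACTION = 0.60


@dataclass(frozen=True)
class PeakResult:
    """Detected LSPR peak with QC flags."""

    wavelength_nm: float
    absorbance: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class AggregationResult:
    """Aggregation index of one well or replicate group.

    ``ai_ratio_percent`` is ``None`` until the result has been normalized
    against the plate's normREF (see :func:`ai_ratio`).
    """

    entity_id: str
    ai: float
    lspr_wavelength_nm: float
    abs_lspr: float
    abs_red1: float
    abs_red2: float
    red1_wavelength_nm: float = RED1_NM
    red2_wavelength_nm: float = RED2_FALLBACK_NM[0]
    ai_ratio_percent: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def wavelength_set(self) -> tuple[float, float, float]:
        return (self.lspr_wavelength_nm, self.red1_wavelength_nm, self.red2_wavelength_nm)


@dataclass(frozen=True)
class AuNPBatch:
    """UV-Vis characterization of a gold-nanoparticle batch."""

    lspr_wavelength_nm: float
    diameter_nm: float
    concentration_nM: float
    batch_id: str = ""
    flags: tuple[str, ...] = ()


def find_lspr_peak(
    spectrum: Spectrum,
    search_window_nm: tuple[float, float] = LSPR_WINDOW_NM,
    smooth_window: int | None = None,
) -> PeakResult:
    """Locate the LSPR maximum inside ``search_window_nm``.

    Raw argmax by default; ``smooth_window`` (odd, 5–11 points) enables a
    light Savitzky-Golay smoother for noisy single wells.  A flat window
    returns its leftmost point flagged ``no_distinct_peak``.  Any local
    maximum *outside* the window taller than 60 % of the main peak flags
    the batch as non-spherical or aggregated (secondary NP populations).
    """
    lo, hi = search_window_nm
    if not spectrum.covers(lo, hi):
        raise PeakDetectionError(
            f"spectrum of well {spectrum.well_id!r} does not cover the LSPR "
            f"search window [{lo}, {hi}] nm"
        )
    w = spectrum.wavelengths_nm
    a = spectrum.absorbances_au
    if smooth_window is not None:
        if smooth_window % 2 == 0 or not 5 <= smooth_window <= 11:
            raise ValueError("smooth_window must be an odd number of points in [5, 11]")
        a = savgol_filter(a, window_length=smooth_window, polyorder=2)
    mask = (w >= lo) & (w <= hi)
    if not mask.any():
        raise PeakDetectionError("no grid points inside the LSPR search window")
    flags: list[str] = []
    seg = a[mask]
    if np.ptp(seg) == 0.0:
        idx = 0
        flags.append("no_distinct_peak")
    else:
        idx = int(np.argmax(seg))
    peak_nm = float(w[mask][idx])
    peak_au = float(seg[idx])

    # secondary-peak screen over the full spectrum
    peaks, _ = find_peaks(a)
    for p in peaks:
        if lo <= w[p] <= hi:
            continue
        if a[p] > SECONDARY_PEAK_FRACTION * peak_au:
            flags.append("secondary_peak_outside_window")
            break
    return PeakResult(wavelength_nm=peak_nm, absorbance=peak_au, flags=tuple(flags))


def resolve_red2(spectrum_or_grid: Spectrum | np.ndarray, red2: float | str = "auto") -> float:
    """Pick the second red-shift wavelength.

    ``"auto"`` walks the fallback order 850 → 800 → 780 nm and returns the
    first wavelength the grid covers; an explicit value is validated
    against coverage.
    """
    if isinstance(spectrum_or_grid, Spectrum):
        grid = spectrum_or_grid.wavelengths_nm
    else:
        grid = np.asarray(spectrum_or_grid, dtype=float)
    if red2 == "auto":
        for cand in RED2_FALLBACK_NM:
            if grid[0] <= cand <= grid[-1]:
                return cand
        raise SpectrumError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] nm covers none of the red-shift "
            f"wavelengths {RED2_FALLBACK_NM}"
        )
    red2 = float(red2)
    if red2 not in RED2_FALLBACK_NM:
        raise ValueError(f"red2 must be one of {RED2_FALLBACK_NM} or 'auto'")
    if not grid[0] <= red2 <= grid[-1]:
        raise SpectrumError(f"grid does not cover the requested red2 = {red2:g} nm")
    return red2


def aggregation_index(
    spectrum: Spectrum,
    lspr_wavelength_nm: float,
    red_wavelengths_nm: tuple[float, float | str] = (RED1_NM, "auto"),
) -> AggregationResult:
    """Compute the aggregation index of one blank-corrected spectrum.

    ``lspr_wavelength_nm`` is the *fixed* LSPR wavelength detected on the
    plate's normREF — aggregated wells have shifted maxima, but the index
    is defined at the monodispersed-particle peak.
    """
    red1, red2 = red_wavelengths_nm
    red1 = float(red1)
    red2 = resolve_red2(spectrum, red2)
    abs_lspr = spectrum.absorbance_at(lspr_wavelength_nm)
    abs_red1 = spectrum.absorbance_at(red1)
    abs_red2 = spectrum.absorbance_at(red2)
    denom = abs_red1 + abs_red2
    if denom <= 0:
        raise UndefinedAIError(
            f"well {spectrum.well_id!r}: Abs({red1:g}) + Abs({red2:g}) = "
            f"{denom:.4g} <= 0 — corrupted or blank well?"
        )
    flags: tuple[str, ...] = ()
    if abs_lspr < LOW_SIGNAL_AU:
        flags = ("low_lspr_absorbance",)
    return AggregationResult(
        entity_id=spectrum.well_id,
        ai=abs_lspr / denom,
        lspr_wavelength_nm=float(lspr_wavelength_nm),
        abs_lspr=abs_lspr,
        abs_red1=abs_red1,
        abs_red2=abs_red2,
        red1_wavelength_nm=red1,
        red2_wavelength_nm=red2,
        flags=flags,
    )


def ai_ratio(sample: AggregationResult, norm_ref: AggregationResult) -> float:
    """AI of a sample as a percentage of the dispersed-AuNP reference AI.

    Both results must have been computed on the identical wavelength set
    (LSPR, 650, red2); mixing sets would silently compare incomparable
    indices, so it is a hard error.
    """
    if sample.wavelength_set != norm_ref.wavelength_set:
        raise WavelengthMismatchError(
            f"wavelength sets differ: sample {sample.wavelength_set} vs "
            f"normREF {norm_ref.wavelength_set}"
        )
    if norm_ref.ai <= 0:
        raise UndefinedAIError("normREF AI must be positive")
    # ratio first: a result normalized against itself is exactly 100 %
    return 100.0 * (sample.ai / norm_ref.ai)


def with_ai_ratio(sample: AggregationResult, norm_ref: AggregationResult) -> AggregationResult:
    """Return a copy of ``sample`` carrying its AI ratio vs ``norm_ref``."""
    return replace(sample, ai_ratio_percent=ai_ratio(sample, norm_ref))


def estimate_aunp_diameter(spectrum: Spectrum, peak: PeakResult | None = None) -> float:
    """AuNP diameter [nm] from the ratio of peak to 450 nm absorbance.

    Uses the empirical relation d = exp(B1 * A_spr/A_450 - B2) for citrate
    gold spheres (valid ~3–120 nm).
    """
    if peak is None:
        peak = find_lspr_peak(spectrum)
    a450 = spectrum.absorbance_at(450.0)
    if a450 <= 0:
        raise SpectrumError(f"A(450 nm) = {a450:.4g} <= 0: cannot size the batch")
    return math.exp(HAISS_B1 * (peak.absorbance / a450) - HAISS_B2)


def estimate_aunp_concentration(
    spectrum: Spectrum,
    diameter_nm: float,
    path_length_cm: float = DEFAULT_PATH_LENGTH_CM,
) -> float:
    """AuNP molar concentration [nM] from A(450) and the diameter.

    The particle number density per ml is
    ``(A450/L) * 1e14 / (d^2 * (C1 + C2*exp(-((d-C3)/C4)^2)))`` with the
    Haiss constants; dividing the per-liter density by Avogadro's number
    gives molarity.  Absorbance is normalized by the optical path
    ``path_length_cm`` (microplate wells are much shorter than a 1 cm
    cuvette).
    """
    if path_length_cm <= 0:
        raise ValueError("path_length_cm must be positive")
    a450 = spectrum.absorbance_at(450.0)
    shape = HAISS_C1 + HAISS_C2 * math.exp(-(((diameter_nm - HAISS_C3) / HAISS_C4) ** 2))
    denom = diameter_nm**2 * shape
    if denom <= 0:
        raise SpectrumError(
            f"diameter {diameter_nm:g} nm outside the validity range of the "
            "UV-Vis concentration relation"
        )
    n_per_ml = (a450 / path_length_cm) * 1e14 / denom
    molar = n_per_ml * 1000.0 / AVOGADRO  # mol/L
    return molar * 1e9  # nM


def qc_aunp_batch(
    norm_ref_spectrum: Spectrum,
    path_length_cm: float = DEFAULT_PATH_LENGTH_CM,
    batch_id: str = "",
) -> AuNPBatch:
    """Full UV-Vis QC of an AuNP batch from its (blank-corrected) spectrum."""
    peak = find_lspr_peak(norm_ref_spectrum)
    flags = list(peak.flags)
    lo, hi = LSPR_WINDOW_NM
    if not lo <= peak.wavelength_nm <= hi:
        flags.append("lspr_outside_expected_window")
    d = estimate_aunp_diameter(norm_ref_spectrum, peak)
    if not HAISS_DIAMETER_RANGE_NM[0] < d < HAISS_DIAMETER_RANGE_NM[1]:
        flags.append("diameter_outside_haiss_range")
    try:
        c = estimate_aunp_concentration(norm_ref_spectrum, d, path_length_cm)
    except SpectrumError:
        c = float("nan")
        flags.append("concentration_estimate_failed")
    return AuNPBatch(
        lspr_wavelength_nm=peak.wavelength_nm,
        diameter_nm=d,
        concentration_nM=c,
        batch_id=batch_id,
        flags=tuple(flags),
    )


def dilution_to_working(batch: AuNPBatch, target_nM: float = 6.0) -> float:
    """Dilution factor that brings the batch to the working concentration.

    The assay adds the particles at 6 nM; a more dilute batch cannot be
    concentrated by dilution, hence the error.
    """
    if target_nM <= 0:
        raise ValueError("target_nM must be positive")
    if batch.concentration_nM < target_nM:
        raise ValueError(
            f"batch at {batch.concentration_nM:.3g} nM is more dilute than the "
            f"{target_nM:g} nM working target"
        )
    return batch.concentration_nM / target_nM
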