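"""Liposome calibration line: AI ratio vs lipid concentration.

Pure phosphatidylcholine (POPC) liposomes mimic vesicles of known lipid
content.  Standards spanning 0.01–0.35 mg/ml lipid produce AI ratios that
increase linearly with concentration under the assay's working
conditions; an ordinary least-squares line through at least five
standards is then *inverted* to convert a sample's AI ratio into a lipid
concentration.  A fresh line is required for every AuNP batch — results
are only comparable within one batch's spectral characteristics.

The calibration abscissa is the concentration of the 25-ul standard
addition *as prepared* (the labels on the standard tubes), not the
in-well concentration after volumetric dilution; samples are corrected
back to the same convention by the titration module's geometry factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, ExtrapolationError

#: assay-validated concentration envelope [mg/ml]
VALIDATED_RANGE_MG_ML = (0.01, 0.35)
#: expected AI ratio of the most concentrated standard (troubleshooting rule)
TOP_STANDARD_BAND_PERCENT = (40.0, 60.0)
#: r^2 below this is flagged (the assay typically reaches ~0.98)
R2_WARNING_THRESHOLD = 0.95
MIN_STANDARDS = 5
#: default grace margin [percentage points] for inverse prediction at range edges
DEFAULT_GRACE_PERCENT = 2.0


@dataclass(frozen=True)
class StandardPoint:
    concentration_mg_ml: float
    ai_ratio_percent: float
    sd: float = 0.0
    n: int = 1


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted AI-ratio-vs-concentration line with its validity window."""

    slope: float  # % per (mg/ml)
    intercept: float  # %
    r_squared: float
    concentration_range_mg_ml: tuple[float, float]
    ai_ratio_range_percent: tuple[float, float]
    red2_wavelength_nm: float
    aunp_batch_id: str = ""
    standards: tuple[StandardPoint, ...] = ()
    warnings: tuple[str, ...] = ()
    fit_method: str = "free OLS"  # line fitted freely, not forced through any point

    @property
    def n_standards(self) -> int:
        return len(self.standards)

    def predict(self, concentration_mg_ml: float) -> float:
        """AI ratio [%] the line predicts at a given lipid concentration."""
        return self.intercept + self.slope * concentration_mg_ml

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "slope_percent_per_mg_ml": self.slope,
            "intercept_percent": self.intercept,
            "r_squared": self.r_squared,
            "concentration_range_mg_ml": list(self.concentration_range_mg_ml),
            "ai_ratio_range_percent": list(self.ai_ratio_range_percent),
            "red2_wavelength_nm": self.red2_wavelength_nm,
            "aunp_batch_id": self.aunp_batch_id,
            "n_standards": self.n_standards,
            "standards": [
                {"concentration_mg_ml": s.concentration_mg_ml,
                 "ai_ratio_percent": s.ai_ratio_percent, "sd": s.sd, "n": s.n}
                for s in self.standards
            ],
            "warnings": list(self.warnings),
            "fit_method": self.fit_method,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            slope=float(d["slope_percent_per_mg_ml"]),
            intercept=float(d["intercept_percent"]),
            r_squared=float(d["r_squared"]),
            concentration_range_mg_ml=tuple(d["concentration_range_mg_ml"]),
            ai_ratio_range_percent=tuple(d["ai_ratio_range_percent"]),
            red2_wavelength_nm=float(d["red2_wavelength_nm"]),
            aunp_batch_id=str(d.get("aunp_batch_id", "")),
            standards=tuple(
                StandardPoint(s["concentration_mg_ml"], s["ai_ratio_percent"],
                              s.get("sd", 0.0), s.get("n", 1))
                for s in d.get("standards", ())
            ),
            warnings=tuple(d.get("warnings", ())),
            fit_method=str(d.get("fit_method", "free OLS")),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def line_csv(self, path: str | Path, n_points: int = 50) -> None:
        """Plot-ready CSV: standards plus the fitted line."""
        lo, hi = self.concentration_range_mg_ml
        grid = np.linspace(lo, hi, n_points)
        fitted = pd.DataFrame(
            {"kind": "fit", "concentration_mg_ml": grid,
             "ai_ratio_percent": self.intercept + self.slope * grid, "sd": np.nan}
        )
        pts = pd.DataFrame(
            {"kind": "standard",
             "concentration_mg_ml": [s.concentration_mg_ml for s in self.standards],
             "ai_ratio_percent": [s.ai_ratio_percent for s in self.standards],
             "sd": [s.sd for s in self.standards]}
        )
        pd.concat([pts, fitted], ignore_index=True).to_csv(path, index=False)


def fit_calibration(
    standards: Sequence[tuple[float, float] | tuple[float, float, float] | StandardPoint],
    red2_nm: float,
    batch_id: str = "",
    allow_outside_validated_range: bool = False,
) -> CalibrationModel:
    """Ordinary least-squares calibration line through the standards.

    ``standards`` is a sequence of ``(concentration mg/ml, mean AI ratio %)``
    pairs, optionally with a replicate standard deviation as third element
    (stored for diagnostics only; the fit is unweighted, as the protocol
    prescribes no weighting).

    Errors: fewer than five distinct concentrations, zero concentration
    spread, or a non-positive fitted slope (a failed liposome batch).
    Warnings (stored on the model): r^2 < 0.95, most concentrated standard
    outside the ~50 % expectation band [40, 60] %, or standards outside
    the assay-validated 0.01–0.35 mg/ml envelope (the latter is an error
    unless ``allow_outside_validated_range``).
    """
    pts: list[StandardPoint] = []
    for s in standards:
        if isinstance(s, StandardPoint):
            pts.append(s)
        else:
            c, r, *rest = s
            pts.append(StandardPoint(float(c), float(r), float(rest[0]) if rest else 0.0))
    pts.sort(key=lambda p: p.concentration_mg_ml)
    conc = np.array([p.concentration_mg_ml for p in pts])
    ratio = np.array([p.ai_ratio_percent for p in pts])

    if len(set(conc.tolist())) < MIN_STANDARDS:
        raise CalibrationError(
            f"insufficient standards: need >= {MIN_STANDARDS} distinct "
            f"concentrations, got {len(set(conc.tolist()))}"
        )
    if np.ptp(conc) == 0:
        raise CalibrationError("zero concentration spread across standards")

    lo_env, hi_env = VALIDATED_RANGE_MG_ML
    warnings_: list[str] = []
    if conc[0] < lo_env or conc[-1] > hi_env:
        msg = (
            f"standards [{conc[0]:g}, {conc[-1]:g}] mg/ml exceed the validated "
            f"envelope [{lo_env:g}, {hi_env:g}] mg/ml"
        )
        if not allow_outside_validated_range:
            raise CalibrationError(msg)
        warnings_.append(msg)

    fit = stats.linregress(conc, ratio)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue) ** 2
    if slope <= 0:
        raise CalibrationError(
            f"non-positive calibration slope ({slope:.3g} %/(mg/ml)) — "
            "AI ratio should increase with lipid concentration; failed liposome batch?"
        )
    if r2 < R2_WARNING_THRESHOLD:
        warnings_.append(f"poor linearity: r^2 = {r2:.3f} < {R2_WARNING_THRESHOLD}")
    top = max(pts, key=lambda p: p.concentration_mg_ml)
    lo_band, hi_band = TOP_STANDARD_BAND_PERCENT
    if not lo_band <= top.ai_ratio_percent <= hi_band:
        warnings_.append(
            f"most concentrated standard at {top.ai_ratio_percent:.1f}% AI ratio, "
            f"outside the expected ~50% band [{lo_band:g}, {hi_band:g}]%"
        )

    c_range = (float(conc[0]), float(conc[-1]))
    ai_range = (intercept + slope * c_range[0], intercept + slope * c_range[1])
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        concentration_range_mg_ml=c_range,
        ai_ratio_range_percent=ai_range,
        red2_wavelength_nm=float(red2_nm),
        aunp_batch_id=batch_id,
        standards=tuple(pts),
        warnings=tuple(warnings_),
    )


def invert_calibration(
    model: CalibrationModel,
    ai_ratio_percent: float,
    grace_percent: float = DEFAULT_GRACE_PERCENT,
) -> float:
    """Inverse prediction: AI ratio [%] -> lipid concentration [mg/ml].

    The result is the *in-well standard-equivalent* concentration (same
    convention as the standards); back-scaling to the original sample is
    the titration module's job.  AI ratios outside the calibrated window
    (plus a small grace margin for replicate noise at the edges) raise an
    extrapolation error naming the valid window.
    """
    lo, hi = model.ai_ratio_range_percent
    if not (lo - grace_percent) <= ai_ratio_percent <= (hi + grace_percent):
        raise ExtrapolationError(
            f"AI ratio {ai_ratio_percent:.2f}% outside the calibrated window "
            f"[{lo:.2f}, {hi:.2f}]% (grace +/-{grace_percent:g} points) — "
            "extrapolation refused"
        )
    return (ai_ratio_percent - model.intercept) / model.slope


def check_batch(model: CalibrationModel, plate_batch_id: str | None) -> None:
    """Assert model/plate AuNP-batch agreement.

    A new calibration line is required for every AuNP batch; quantifying a
    plate against another batch's line is a hard error.  Plates that do
    not declare a batch are let through (cannot be checked).
    """
    if plate_batch_id and model.aunp_batch_id and plate_batch_id != model.aunp_batch_id:
        raise CalibrationError(
            f"calibration was built for AuNP batch {model.aunp_batch_id!r} but the "
            f"plate declares batch {plate_batch_id!r}; create a new calibration "
            "line for each batch"
        )
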