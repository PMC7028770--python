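"""Microplate absorbance spectra: reading, validation, blank correction.

The raw observable of the assay is one absorbance spectrum per well of a
96-well plate, exported by the reader as a CSV table.  Two dialects are
accepted:

* **long** — columns ``well,wavelength_nm,absorbance`` (the canonical
  on-disk format, also what :func:`write_long_csv` emits);
* **wide** — first column ``wavelength_nm``, one additional column per
  well.

A companion layout file (YAML or JSON) assigns each well a role: blank,
reference (normREF / intREF), calibration standard (with its lipid
concentration) or sample (with its pre-dilution factor).  Wells sharing a
``replicate_group`` are averaged downstream.

All spectra on a plate must share one strictly increasing wavelength grid
covering at least 450–780 nm (full 400–900 nm preferred), so that the
aggregation-index wavelengths (LSPR peak, 650 nm, 850/800/780 nm) can be
sampled by linear interpolation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AssayWarning, LayoutError, SpectrumError

LONG_COLUMNS = ("well", "wavelength_nm", "absorbance")
#: minimum wavelength coverage needed to compute an AI with red2 fallback
REQUIRED_COVERAGE_NM = (450.0, 780.0)
#: full coverage the protocol asks the reader for
PREFERRED_COVERAGE_NM = (400.0, 900.0)
#: LSPR search window for citrate-capped gold spheres
LSPR_WINDOW_NM = (500.0, 545.0)
#: below this absorbance at the LSPR region a well is suspiciously dilute
LOW_SIGNAL_AU = 0.05
#: replicate coefficient-of-variation above which a group is flagged
CV_FLAG_THRESHOLD = 0.10


@dataclass(eq=False)
class Spectrum:
    """One well's absorbance vs wavelength.

    Parameters
    ----------
    wavelengths_nm:
        Strictly increasing wavelengths in nm, length >= 2.
    absorbances_au:
        Absorbance (optical density) at each wavelength, same length.
    well_id:
        Plate-well label, e.g. ``"A1"``.
    """

    wavelengths_nm: np.ndarray
    absorbances_au: np.ndarray
    well_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        a = np.asarray(self.absorbances_au, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise SpectrumError(
                f"well {self.well_id!r}: wavelengths and absorbances must be "
                f"1-D and equal length (got {w.shape} vs {a.shape})"
            )
        if w.size < 2:
            raise SpectrumError(f"well {self.well_id!r}: need at least 2 points")
        if not np.all(np.diff(w) > 0):
            raise SpectrumError(f"well {self.well_id!r}: wavelengths not strictly increasing")
        if not (np.isfinite(w).all() and np.isfinite(a).all()):
            raise SpectrumError(f"well {self.well_id!r}: non-finite values")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "absorbances_au", a)

    def covers(self, lo_nm: float, hi_nm: float) -> bool:
        return self.wavelengths_nm[0] <= lo_nm and self.wavelengths_nm[-1] >= hi_nm

    def absorbance_at(self, wavelength_nm: float) -> float:
        """Absorbance at an arbitrary wavelength, linearly interpolated.

        Plate readers export various steps (1, 2, 5 nm); off-grid
        wavelengths are interpolated between neighbouring grid points.
        """
        w = self.wavelengths_nm
        if wavelength_nm < w[0] or wavelength_nm > w[-1]:
            raise SpectrumError(
                f"well {self.well_id!r}: {wavelength_nm} nm outside the "
                f"measured range [{w[0]}, {w[-1]}] nm"
            )
        return float(np.interp(wavelength_nm, w, self.absorbances_au))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.well_id == other.well_id
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.absorbances_au, other.absorbances_au)
        )


class Role(Enum):
    """Role of a well on the plate."""

    BLANK = "BLANK"
    NORM_REF = "NORM_REF"
    INT_REF = "INT_REF"
    STANDARD = "STANDARD"
    SAMPLE = "SAMPLE"


_ROLE_ALIASES = {
    "blank": Role.BLANK,
    "normref": Role.NORM_REF,
    "intref": Role.INT_REF,
    "standard": Role.STANDARD,
    "sample": Role.SAMPLE,
}


def parse_role(text: str) -> Role:
    key = str(text).strip().lower().replace("_", "").replace("-", "")
    try:
        return _ROLE_ALIASES[key]
    except KeyError:
        raise LayoutError(f"unknown well role {text!r}") from None


@dataclass(frozen=True)
class LayoutEntry:
    """One well's assignment in the plate layout."""

    well: str
    role: Role
    replicate_group: str = ""
    concentration_mg_per_ml: float | None = None  # STANDARD only
    dilution_factor: float | None = None  # SAMPLE only (>= 1)
    sample_id: str | None = None  # SAMPLE only

    def with_default_group(self) -> "LayoutEntry":
        if self.replicate_group:
            return self
        if self.role is Role.BLANK:
            group = "blank"
        elif self.role is Role.NORM_REF:
            group = "normREF"
        elif self.role is Role.INT_REF:
            group = "intREF"
        elif self.role is Role.STANDARD:
            group = f"std-{self.concentration_mg_per_ml:g}"
        else:
            group = f"{self.sample_id}:{self.dilution_factor:g}"
        return replace(self, replicate_group=group)


@dataclass(frozen=True)
class PlateLayout:
    """Maps wells to roles with concentrations / dilution factors.

    Invariants enforced on construction: at least one blank well, exactly
    one normREF replicate group and exactly one intREF replicate group
    (the three reference points of the assay), positive standard
    concentrations and sample pre-dilution factors >= 1.
    """

    entries: tuple[LayoutEntry, ...]
    aunp_batch_id: str | None = None

    def __post_init__(self) -> None:
        entries = tuple(e.with_default_group() for e in self.entries)
        object.__setattr__(self, "entries", entries)
        seen: set[str] = set()
        for e in entries:
            if e.well in seen:
                raise LayoutError(f"duplicate well id {e.well!r} in layout")
            seen.add(e.well)
            if e.role is Role.STANDARD:
                if e.concentration_mg_per_ml is None or e.concentration_mg_per_ml <= 0:
                    raise LayoutError(
                        f"standard well {e.well!r} needs a positive "
                        f"concentration_mg_per_ml (got {e.concentration_mg_per_ml})"
                    )
            if e.role is Role.SAMPLE:
                if e.sample_id is None:
                    raise LayoutError(f"sample well {e.well!r} needs a sample_id")
                if e.dilution_factor is None or e.dilution_factor < 1:
                    raise LayoutError(
                        f"sample well {e.well!r} needs dilution_factor >= 1 "
                        f"(got {e.dilution_factor})"
                    )
        if not self.by_role(Role.BLANK):
            raise LayoutError("layout needs at least one BLANK well")
        for role, name in ((Role.NORM_REF, "normREF"), (Role.INT_REF, "intREF")):
            groups = {e.replicate_group for e in self.by_role(role)}
            if len(groups) != 1:
                raise LayoutError(
                    f"layout needs exactly one {name} replicate group "
                    f"(found {len(groups)})"
                )

    # -- accessors ---------------------------------------------------------
    def wells(self) -> list[str]:
        return [e.well for e in self.entries]

    def entry(self, well: str) -> LayoutEntry:
        for e in self.entries:
            if e.well == well:
                return e
        raise LayoutError(f"well {well!r} not in layout")

    def by_role(self, role: Role) -> list[LayoutEntry]:
        return [e for e in self.entries if e.role is role]

    def replicate_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for e in self.entries:
            groups.setdefault(e.replicate_group, []).append(e.well)
        return groups

    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for e in self.by_role(Role.SAMPLE):
            if e.sample_id not in out:
                out.append(e.sample_id)  # type: ignore[arg-type]
        return out

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "PlateLayout":
        raw = yaml.safe_load(Path(path).read_text())  # JSON is a YAML subset
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: object) -> "PlateLayout":
        if isinstance(raw, Mapping):
            batch = raw.get("aunp_batch_id")
            rows = raw.get("wells")
        else:
            batch, rows = None, raw
        if not isinstance(rows, Sequence) or not rows:
            raise LayoutError("layout file must contain a non-empty list of wells")
        entries = []
        for row in rows:
            if not isinstance(row, Mapping) or "well" not in row or "role" not in row:
                raise LayoutError(f"layout row missing 'well'/'role': {row!r}")
            entries.append(
                LayoutEntry(
                    well=str(row["well"]),
                    role=parse_role(row["role"]),
                    replicate_group=str(row.get("replicate_group") or ""),
                    concentration_mg_per_ml=_opt_float(row.get("concentration_mg_per_ml")),
                    dilution_factor=_opt_float(row.get("dilution_factor")),
                    sample_id=(None if row.get("sample_id") is None else str(row["sample_id"])),
                )
            )
        return cls(entries=tuple(entries), aunp_batch_id=batch)

    def to_dict(self) -> dict:
        rows = []
        for e in self.entries:
            row: dict[str, object] = {"well": e.well, "role": e.role.value,
                                      "replicate_group": e.replicate_group}
            if e.concentration_mg_per_ml is not None:
                row["concentration_mg_per_ml"] = e.concentration_mg_per_ml
            if e.dilution_factor is not None:
                row["dilution_factor"] = e.dilution_factor
            if e.sample_id is not None:
                row["sample_id"] = e.sample_id
            rows.append(row)
        out: dict[str, object] = {"wells": rows}
        if self.aunp_batch_id is not None:
            out["aunp_batch_id"] = self.aunp_batch_id
        return out

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _opt_float(x: object) -> float | None:
    return None if x is None else float(x)


@dataclass(eq=False)
class PlateSpectra:
    """A plate layout together with one spectrum per well on a common grid."""

    layout: PlateLayout
    spectra: dict[str, Spectrum]
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        missing = [w for w in self.layout.wells() if w not in self.spectra]
        if missing:
            raise LayoutError(f"missing spectrum for well(s): {', '.join(missing)}")
        extra = sorted(set(self.spectra) - set(self.layout.wells()))
        if extra:
            warnings.warn(
                f"spectra present for wells not in layout (ignored): {', '.join(extra)}",
                AssayWarning,
                stacklevel=2,
            )
            self.spectra = {w: s for w, s in self.spectra.items() if w not in extra}
        grid = None
        for w in self.layout.wells():
            s = self.spectra[w]
            if grid is None:
                grid = s.wavelengths_nm
            elif not np.array_equal(grid, s.wavelengths_nm):
                raise SpectrumError(
                    f"well {w!r} is on a different wavelength grid than the rest "
                    "of the plate"
                )
        assert grid is not None
        lo, hi = REQUIRED_COVERAGE_NM
        if not (grid[0] <= lo and grid[-1] >= hi):
            raise SpectrumError(
                f"wavelength coverage [{grid[0]:g}, {grid[-1]:g}] nm is narrower "
                f"than the required [{lo:g}, {hi:g}] nm"
            )

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.spectra[self.layout.wells()[0]].wavelengths_nm

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateSpectra):
            return NotImplemented
        return (
            self.layout == other.layout
            and self.blank_corrected == other.blank_corrected
            and set(self.spectra) == set(other.spectra)
            and all(self.spectra[w] == other.spectra[w] for w in self.spectra)
        )


def read_plate(spectra_file: str | Path, layout_file: str | Path) -> PlateSpectra:
    """Read a plate export plus its layout into a :class:`PlateSpectra`.

    The CSV dialect (long vs wide) is autodetected from the header.  All
    wells must share one wavelength grid; wells named in the layout but
    absent from the export are an error.
    """
    layout = PlateLayout.from_file(layout_file)
    spectra = read_spectra_csv(spectra_file)
    return PlateSpectra(layout=layout, spectra=spectra, blank_corrected=False)


def read_spectra_csv(spectra_file: str | Path) -> dict[str, Spectrum]:
    """Read a long- or wide-format spectra CSV into ``{well: Spectrum}``."""
    path = Path(spectra_file)
    with path.open() as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
    if set(LONG_COLUMNS).issubset(header):
        return _read_long(path)
    if header and header[0] == "wavelength_nm" and len(header) > 1:
        dupes = {c for c in header[1:] if header[1:].count(c) > 1}
        if dupes:
            raise LayoutError(f"duplicate well column(s) in wide CSV: {sorted(dupes)}")
        return _read_wide(path)
    raise SpectrumError(
        "unrecognized spectra CSV header: expected long format "
        f"{LONG_COLUMNS} or wide format ('wavelength_nm', <well>, ...)"
    )


def _read_long(path: Path) -> dict[str, Spectrum]:
    df = pd.read_csv(path, float_precision="round_trip")
    df = df[list(LONG_COLUMNS)]
    if df.duplicated(subset=["well", "wavelength_nm"]).any():
        raise LayoutError(f"{path.name}: duplicate (well, wavelength) rows")
    out: dict[str, Spectrum] = {}
    for well, sub in df.groupby("well", sort=False):
        sub = sub.sort_values("wavelength_nm")
        out[str(well)] = Spectrum(
            wavelengths_nm=sub["wavelength_nm"].to_numpy(dtype=float),
            absorbances_au=sub["absorbance"].to_numpy(dtype=float),
            well_id=str(well),
        )
    return out


def _read_wide(path: Path) -> dict[str, Spectrum]:
    df = pd.read_csv(path, float_precision="round_trip").sort_values("wavelength_nm")
    w = df["wavelength_nm"].to_numpy(dtype=float)
    return {
        str(col): Spectrum(wavelengths_nm=w, absorbances_au=df[col].to_numpy(dtype=float),
                           well_id=str(col))
        for col in df.columns
        if col != "wavelength_nm"
    }


def write_long_csv(plate: PlateSpectra, path: str | Path) -> None:
    """Write all plate spectra in the canonical long CSV format."""
    frames = []
    for well in plate.layout.wells():
        s = plate.spectra[well]
        frames.append(
            pd.DataFrame(
                {"well": well, "wavelength_nm": s.wavelengths_nm,
                 "absorbance": s.absorbances_au}
            )
        )
    # %.17g keeps the write/read cycle bit-exact for float64 absorbances
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def subtract_blank(plate: PlateSpectra) -> PlateSpectra:
    """Subtract the mean blank spectrum from every well.

    Standard UV-Vis practice: the blank (water) well's spectrum is
    measured and subtracted from all sample and reference wells.  Negative
    corrected absorbances are retained (not clipped) so that the
    aggregation index stays a pure function of the data.

    Raises on double correction.  Warns (does not fail) when the blank
    exceeds a well's absorbance over the LSPR region, or when a corrected
    well is nearly flat there (too dilute / misloaded well).
    """
    if plate.blank_corrected:
        raise SpectrumError("plate is already blank-corrected")
    blanks = [plate.spectra[e.well] for e in plate.layout.by_role(Role.BLANK)]
    blank_mean = np.mean([b.absorbances_au for b in blanks], axis=0)

    lo, hi = LSPR_WINDOW_NM
    grid = plate.wavelengths_nm
    window = (grid >= lo) & (grid <= hi)
    blank_peak = float(blank_mean[window].max()) if window.any() else 0.0

    corrected: dict[str, Spectrum] = {}
    for e in plate.layout.entries:
        s = plate.spectra[e.well]
        new = Spectrum(
            wavelengths_nm=s.wavelengths_nm,
            absorbances_au=s.absorbances_au - blank_mean,
            well_id=s.well_id,
        )
        corrected[e.well] = new
        if e.role is Role.BLANK or not window.any():
            continue
        raw_peak = float(s.absorbances_au[window].max())
        if blank_peak > raw_peak:
            warnings.warn(
                f"well {e.well}: blank absorbance exceeds the well's absorbance "
                "over the LSPR region",
                AssayWarning,
                stacklevel=2,
            )
        if float(new.absorbances_au[window].max()) < LOW_SIGNAL_AU:
            warnings.warn(
                f"well {e.well}: corrected absorbance < {LOW_SIGNAL_AU} AU at the "
                "LSPR region (too dilute / misloaded well?)",
                AssayWarning,
                stacklevel=2,
            )
    return PlateSpectra(layout=plate.layout, spectra=corrected, blank_corrected=True)


def aggregate_replicates(
    plate: PlateSpectra, statistic_level: str = "index"
) -> dict[str, object]:
    """Group wells by replicate group.

    ``statistic_level="index"`` (default) returns ``{group: [Spectrum, ...]}``
    so that the aggregation index is computed per well and averaged
    afterwards — the AI is a ratio, and the protocol runs triplicates per
    sample, so averaging at the index level is the faithful reading.

    ``statistic_level="spectrum"`` instead averages the replicate spectra
    pointwise first and returns ``{group: Spectrum}``; available for
    sensitivity analysis.
    """
    if not plate.blank_corrected:
        raise SpectrumError("aggregate_replicates needs a blank-corrected plate")
    if statistic_level not in ("index", "spectrum"):
        raise ValueError(f"unknown statistic_level {statistic_level!r}")
    groups = plate.layout.replicate_groups()
    out: dict[str, object] = {}
    for group, wells in groups.items():
        if not wells:
            raise LayoutError(f"replicate group {group!r} has no wells")
        members = [plate.spectra[w] for w in wells]
        if statistic_level == "index":
            out[group] = members
        else:
            mean = np.mean([m.absorbances_au for m in members], axis=0)
            out[group] = Spectrum(
                wavelengths_nm=members[0].wavelengths_nm,
                absorbances_au=mean,
                well_id=group,
            )
    return out


@dataclass(frozen=True)
class GroupStats:
    """Replicate summary for one scalar quantity (e.g. a group's AI values)."""

    mean: float
    sd: float
    n: int
    flags: tuple[str, ...] = ()


def summarize_values(
    values: Sequence[float], cv_threshold: float = CV_FLAG_THRESHOLD
) -> GroupStats:
    """Mean and sample standard deviation of replicate values, with QC flags.

    A single-well group reports sd = 0 with a ``single_replicate`` flag; a
    coefficient of variation above ``cv_threshold`` adds a
    ``high_replicate_scatter`` flag (flag only, never an error — the
    protocol gives no numeric replicate-agreement rule).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise LayoutError("replicate group of size 0")
    flags: list[str] = []
    mean = float(vals.mean())
    if vals.size == 1:
        return GroupStats(mean=mean, sd=0.0, n=1, flags=("single_replicate",))
    sd = float(vals.std(ddof=1))
    if mean != 0 and sd / abs(mean) > cv_threshold:
        flags.append("high_replicate_scatter")
    return GroupStats(mean=mean, sd=sd, n=int(vals.size), flags=tuple(flags))
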