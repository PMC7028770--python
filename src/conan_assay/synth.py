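"""Synthetic plate generator: controllable aggregation states, no instrument.

Real AuNP spectra red-shift and broaden continuously as particles
cluster.  The generator emulates that with a two-band surrogate: each
well's spectrum is a convex mix of a monomer Gaussian (center 519 nm) and
a broad aggregate Gaussian (center 680 nm, so both 650 and 850 nm carry
signal), plus a flat baseline and optional additive white noise:

    A(lambda) = baseline + (1 - phi) * monomer(lambda)
                         + phi * aggregate(lambda) + noise

``phi`` in [0, 1] is the aggregated fraction.  The noise-free AI ratio is
a strictly decreasing function of ``phi``, so any target AI ratio within
the attainable range can be hit by root finding — which is how scenarios
(calibration line, pure / contaminated / vesicle-free / over-diluted
dilution series) prescribe their trajectories.  Gaussian bands are chosen
over physically truer Lorentzians because they give simple closed forms
for test oracles; spectral fidelity is a non-goal.

Ground truth (per-well phi, target AI ratios, the generating line, the
true sample concentration) is always emitted next to the data so that
tests and benchmarks never have to re-derive it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import SimulationError
from .spectra import LayoutEntry, PlateLayout, PlateSpectra, Role, Spectrum, write_long_csv
from .titration import ASSAY_GEOMETRY_FACTOR

#: wavelength grid of generated exports [nm]
GRID_NM = np.arange(400.0, 901.0, 1.0)


@dataclass(frozen=True)
class SpectralModel:
    """Two-band surrogate of AuNP extinction with aggregation state."""

    monomer_center_nm: float = 519.0
    monomer_width_nm: float = 30.0
    monomer_height_au: float = 1.0  # plate-read amplitude at the 6 nM working level
    aggregate_center_nm: float = 680.0
    aggregate_width_nm: float = 110.0
    aggregate_height_fraction: float = 0.75
    baseline_au: float = 0.02
    noise_sd_au: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.monomer_width_nm, self.aggregate_width_nm,
               self.monomer_height_au, self.aggregate_height_fraction) <= 0:
            raise SimulationError("band widths and heights must be positive")
        if self.noise_sd_au < 0:
            raise SimulationError("noise sd must be non-negative")

    # closed-form band values (exact; used both for generation and oracles)
    def monomer_band(self, wavelength_nm: float | np.ndarray) -> float | np.ndarray:
        w = np.asarray(wavelength_nm, dtype=float)
        out = self.monomer_height_au * np.exp(
            -((w - self.monomer_center_nm) ** 2) / (2.0 * self.monomer_width_nm**2)
        )
        return out if out.ndim else float(out)

    def aggregate_band(self, wavelength_nm: float | np.ndarray) -> float | np.ndarray:
        w = np.asarray(wavelength_nm, dtype=float)
        h = self.monomer_height_au * self.aggregate_height_fraction
        out = h * np.exp(
            -((w - self.aggregate_center_nm) ** 2) / (2.0 * self.aggregate_width_nm**2)
        )
        return out if out.ndim else float(out)

    def clean_absorbance(self, wavelength_nm: float | np.ndarray, phi: float):
        """Noise-free, baseline-free absorbance of the band mix."""
        return (1.0 - phi) * self.monomer_band(wavelength_nm) + phi * self.aggregate_band(
            wavelength_nm
        )


def spectrum_from_phi(
    model: SpectralModel,
    phi: float,
    with_noise: bool = True,
    rng: np.random.Generator | None = None,
    well_id: str = "",
) -> Spectrum:
    """One well's spectrum at aggregated fraction ``phi`` on the 400–900 grid.

    Without an explicit ``rng`` the model seed is used, making repeated
    calls bitwise identical (the determinism contract); pass a shared
    generator to draw independent wells from one stream.
    """
    if not 0.0 <= phi <= 1.0:
        raise SimulationError(f"phi = {phi} outside [0, 1]")
    a = model.baseline_au + np.asarray(model.clean_absorbance(GRID_NM, phi))
    if with_noise and model.noise_sd_au > 0:
        if rng is None:
            rng = np.random.default_rng(model.seed)
        a = a + rng.normal(0.0, model.noise_sd_au, size=GRID_NM.size)
    return Spectrum(wavelengths_nm=GRID_NM.copy(), absorbances_au=a, well_id=well_id)


def ai_of_phi(model: SpectralModel, phi: float, red2_nm: float = 850.0) -> float:
    """Noise-free aggregation index of the band mix (closed form).

    Sampled at the monomer center (the normREF LSPR wavelength), 650 nm
    and ``red2_nm``, baseline included — exactly what the analysis
    pipeline sees on noise-free generated data.
    """
    lspr = model.monomer_center_nm
    num = model.baseline_au + float(model.clean_absorbance(lspr, phi))
    den = (
        2.0 * model.baseline_au
        + float(model.clean_absorbance(650.0, phi))
        + float(model.clean_absorbance(red2_nm, phi))
    )
    return num / den


def ai_ratio_of_phi(model: SpectralModel, phi: float, red2_nm: float = 850.0) -> float:
    """Noise-free AI ratio [%] relative to the dispersed (phi = 0) state."""
    return 100.0 * ai_of_phi(model, phi, red2_nm) / ai_of_phi(model, 0.0, red2_nm)


def attainable_ai_ratio_range(model: SpectralModel, red2_nm: float = 850.0) -> tuple[float, float]:
    """(floor at phi = 1, ceiling = 100 at phi = 0) of the AI-ratio curve."""
    return (ai_ratio_of_phi(model, 1.0, red2_nm), 100.0)


def phi_for_ai_ratio(
    model: SpectralModel, target_ai_ratio_percent: float, red2_nm: float = 850.0
) -> float:
    """Invert the strictly decreasing AI-ratio(phi) curve by root finding.

    Exact at the endpoints; elsewhere solved with Brent's method far below
    the 0.1-percentage-point contract of this operation.
    """
    lo, hi = attainable_ai_ratio_range(model, red2_nm)
    t = float(target_ai_ratio_percent)
    if not lo <= t <= hi:
        raise SimulationError(
            f"target AI ratio {t:g}% outside the attainable range [{lo:.2f}, {hi:.2f}]%"
        )
    if t == hi:
        return 0.0
    if t == lo:
        return 1.0
    return float(brentq(lambda p: ai_ratio_of_phi(model, p, red2_nm) - t, 0.0, 1.0,
                        xtol=1e-13, rtol=8.9e-16))


class ScenarioKind(Enum):
    CALIBRATION = "CALIBRATION"
    PURE_CONCENTRATED = "PURE_CONCENTRATED"
    PURE = "PURE"
    CONTAMINATED = "CONTAMINATED"
    NO_EV = "NO_EV"
    OVERDILUTED = "OVERDILUTED"


#: defaults per scenario kind: (sample lipid conc [mg/ml], dilution factors)
_SAMPLE_DEFAULTS: dict[ScenarioKind, tuple[float | None, tuple[float, ...]]] = {
    ScenarioKind.PURE: (1.5, (10.0, 30.0, 100.0)),
    ScenarioKind.PURE_CONCENTRATED: (6.4, (1.0, 10.0, 100.0)),
    ScenarioKind.CONTAMINATED: (None, (10.0, 30.0, 100.0)),
    ScenarioKind.NO_EV: (None, (10.0, 100.0)),
    ScenarioKind.OVERDILUTED: (None, (10.0, 300.0, 1000.0)),
}


@dataclass(frozen=True)
class Scenario:
    """Prescription of one synthetic plate.

    The calibration response is affine in concentration by construction
    — AI ratio runs from ``ai_at_c_min`` (near the aggregated floor) at
    0.01 mg/ml up to ``ai_at_c_max`` (~50 %, matching the expectation for
    the most concentrated standard) at 0.35 mg/ml — so that an OLS line
    is the correct calibration model.  Sample trajectories follow the
    scenario kind: pure series track the same line through their in-well
    readouts; contaminated series sit flat in the 60–70 % plateau;
    vesicle-free series sit at the intREF level; over-diluted series dip
    and then rise again beyond 1:500.
    """

    kind: ScenarioKind
    seed: int = 0
    standard_concentrations_mg_ml: tuple[float, ...] = (0.35, 0.20, 0.10, 0.05, 0.01)
    #: standards ride on every plate by default — the protocol calibrates and
    #: grades within one session against the same references and AuNP batch
    include_standards: bool = True
    replicates: int = 3
    n_blanks: int = 3
    sample_id: str = "S1"
    sample_lipid_mg_ml: float | None = None
    dilution_factors: tuple[float, ...] | None = None
    int_ref_ai_ratio_percent: float = 47.0
    contaminated_level_percent: float = 65.0
    #: anchors of the affine concentration -> AI ratio response
    ai_at_c_min_percent: float = 8.0
    ai_at_c_max_percent: float = 50.0
    #: explicit AI-ratio targets of the over-diluted trajectory
    overdiluted_targets_percent: tuple[float, ...] = (32.0, 22.0, 30.0)
    aunp_batch_id: str = "batch-1"

    def __post_init__(self) -> None:
        if self.kind is not ScenarioKind.CALIBRATION:
            conc, dil = _SAMPLE_DEFAULTS[self.kind]
            if self.sample_lipid_mg_ml is None:
                object.__setattr__(self, "sample_lipid_mg_ml", conc)
            if self.dilution_factors is None:
                object.__setattr__(self, "dilution_factors", dil)
        if self.kind is ScenarioKind.CONTAMINATED and not (
            60.0 <= self.contaminated_level_percent <= 70.0
        ):
            raise SimulationError("contaminated plateau must sit in [60, 70]%")

    # affine concentration -> AI ratio response of the assay surrogate
    def line_slope_intercept(self) -> tuple[float, float]:
        c = sorted(self.standard_concentrations_mg_ml)
        c_min, c_max = 0.01, 0.35
        slope = (self.ai_at_c_max_percent - self.ai_at_c_min_percent) / (c_max - c_min)
        intercept = self.ai_at_c_min_percent - slope * c_min
        return slope, intercept

    def target_ai_for_concentration(self, conc_mg_ml: float, model: SpectralModel) -> float:
        slope, intercept = self.line_slope_intercept()
        lo, hi = attainable_ai_ratio_range(model)
        target = intercept + slope * conc_mg_ml
        return float(np.clip(target, lo + 0.5, hi - 0.5))


@dataclass
class GeneratedPlate:
    """In-memory product of :func:`generate_plate` plus file writers."""

    plate: PlateSpectra  # raw (not blank-corrected)
    truth: dict

    def write(self, out_dir: str | Path, basename: str = "plate") -> dict[str, Path]:
        """Write plate.csv (long), plate.layout.yaml and plate.truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "spectra": out / f"{basename}.csv",
            "layout": out / f"{basename}.layout.yaml",
            "truth": out / f"{basename}.truth.json",
        }
        write_long_csv(self.plate, paths["spectra"])
        self.plate.layout.to_file(paths["layout"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1))
        return paths


def _well_names() -> list[str]:
    return [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def generate_plate(
    scenario: Scenario,
    model: SpectralModel = SpectralModel(),
    with_noise: bool = True,
    rng: np.random.Generator | None = None,
) -> GeneratedPlate:
    """Emit a full synthetic plate for one scenario.

    Every plate carries blanks, a normREF triplicate (phi = 0), an intREF
    triplicate hitting the configured 45–50 % AI ratio, optionally
    triplicate standards on the affine calibration response, and — for
    sample scenarios — the sample's dilution series.  Identical seeds
    yield identical plates.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    names = iter(_well_names())
    entries: list[LayoutEntry] = []
    spectra: dict[str, Spectrum] = {}
    truth_wells: dict[str, dict] = {}

    def add_well(role: Role, phi: float | None, group: str, *, conc: float | None = None,
                 dilution: float | None = None, sample_id: str | None = None,
                 target: float | None = None) -> None:
        try:
            well = next(names)
        except StopIteration:  # pragma: no cover - 96 wells is plenty
            raise SimulationError("scenario does not fit on a 96-well plate") from None
        entries.append(
            LayoutEntry(well=well, role=role, replicate_group=group,
                        concentration_mg_per_ml=conc, dilution_factor=dilution,
                        sample_id=sample_id)
        )
        if phi is None:
            # water blank: no particles, hence no scattering baseline —
            # baseline_au models turbidity of the colloid itself and
            # survives blank correction, keeping AI denominators finite
            a = np.zeros(GRID_NM.size)
            if with_noise and model.noise_sd_au > 0:
                a = a + rng.normal(0.0, model.noise_sd_au, size=GRID_NM.size)
            spectra[well] = Spectrum(GRID_NM.copy(), a, well_id=well)
        else:
            spectra[well] = spectrum_from_phi(model, phi, with_noise, rng, well_id=well)
        truth_wells[well] = {
            "role": role.value, "phi": phi, "target_ai_ratio_percent": target,
            "concentration_mg_ml": conc, "dilution_factor": dilution,
        }

    for _ in range(scenario.n_blanks):
        add_well(Role.BLANK, None, "blank")
    for _ in range(scenario.replicates):
        add_well(Role.NORM_REF, 0.0, "normREF", target=100.0)
    phi_int = phi_for_ai_ratio(model, scenario.int_ref_ai_ratio_percent)
    for _ in range(scenario.replicates):
        add_well(Role.INT_REF, phi_int, "intREF",
                 target=scenario.int_ref_ai_ratio_percent)

    if scenario.include_standards:
        for conc in scenario.standard_concentrations_mg_ml:
            target = scenario.target_ai_for_concentration(conc, model)
            phi = phi_for_ai_ratio(model, target)
            for _ in range(scenario.replicates):
                add_well(Role.STANDARD, phi, f"std-{conc:g}", conc=conc, target=target)

    sample_targets: list[dict] = []
    if scenario.kind is not ScenarioKind.CALIBRATION:
        assert scenario.dilution_factors is not None
        for i, d in enumerate(scenario.dilution_factors):
            target = _sample_target(scenario, model, i, d)
            phi = phi_for_ai_ratio(model, target)
            for _ in range(scenario.replicates):
                add_well(Role.SAMPLE, phi, f"{scenario.sample_id}:{d:g}",
                         dilution=d, sample_id=scenario.sample_id, target=target)
            sample_targets.append(
                {"dilution_factor": d, "target_ai_ratio_percent": target, "phi": phi}
            )

    layout = PlateLayout(entries=tuple(entries), aunp_batch_id=scenario.aunp_batch_id)
    plate = PlateSpectra(layout=layout, spectra=spectra, blank_corrected=False)
    slope, intercept = scenario.line_slope_intercept()
    truth = {
        "kind": scenario.kind.value,
        "seed": scenario.seed,
        "noise_sd_au": model.noise_sd_au if with_noise else 0.0,
        "int_ref_target_percent": scenario.int_ref_ai_ratio_percent,
        "response_line": {"slope_percent_per_mg_ml": slope, "intercept_percent": intercept},
        "assay_geometry_factor": ASSAY_GEOMETRY_FACTOR,
        "sample": (
            None
            if scenario.kind is ScenarioKind.CALIBRATION
            else {
                "sample_id": scenario.sample_id,
                "lipid_mg_ml": scenario.sample_lipid_mg_ml,
                "points": sample_targets,
            }
        ),
        "wells": truth_wells,
    }
    return GeneratedPlate(plate=plate, truth=truth)


def _sample_target(scenario: Scenario, model: SpectralModel, index: int, dilution: float) -> float:
    """Target AI ratio of one dilution point, by scenario kind."""
    kind = scenario.kind
    if kind in (ScenarioKind.PURE, ScenarioKind.PURE_CONCENTRATED):
        assert scenario.sample_lipid_mg_ml is not None
        # in-well standard-equivalent readout of the diluted sample
        readout = scenario.sample_lipid_mg_ml / (ASSAY_GEOMETRY_FACTOR * dilution)
        return scenario.target_ai_for_concentration(readout, model)
    if kind is ScenarioKind.CONTAMINATED:
        return scenario.contaminated_level_percent
    if kind is ScenarioKind.NO_EV:
        return scenario.int_ref_ai_ratio_percent
    if kind is ScenarioKind.OVERDILUTED:
        targets = scenario.overdiluted_targets_percent
        if len(targets) != len(scenario.dilution_factors or ()):
            raise SimulationError(
                "OVERDILUTED needs one target AI ratio per dilution factor"
            )
        return targets[index]
    raise SimulationError(f"unsupported scenario kind {kind}")  # pragma: no cover
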