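"""Stoichiometric titration: lipid concentration -> vesicle number.

Once a preparation is graded pure and its in-well lipid concentration has
been read off the calibration line, the vesicle count follows from simple
stoichiometry.  A spherical vesicle of mean diameter ``d`` exposes two
bilayer leaflets of total area ``2 * pi * d^2``; dividing by the area per
phospholipid headgroup ``a`` (0.65 nm^2 by default) gives the lipids per
vesicle

    N_l = 2 * pi * d^2 / a.

The lipid mass concentration ``l`` [g/L] from the assay then converts via
POPC molarity ``l / M``, lipid molecules per liter ``(l / M) * N_a``,
vesicles per liter ``(l / M) * N_a / N_l`` and finally vesicle molarity

    EVs_[M] = l / (M * N_l),

with ``M`` the POPC molar mass (760.08 g/mol) and ``N_a`` Avogadro's
number.  The long chain and the compact form are algebraically identical;
both are computed and cross-checked to machine precision.

Because a sample occupies only 2 ul of the 25-ul addition that standards
fill entirely, a sample's standard-equivalent readout must be scaled up
by the assay geometry factor 25/2 = 12.5 — and by any pre-dilution —
before titration.

The titration refuses to run without a pure purity verdict carrying a
quantification point: purity grading is the gatekeeper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .calibration import CalibrationModel, check_batch, invert_calibration
from .errors import TitrationError, TitrationRefusedError
from .purity import PURE_VERDICTS, PurityVerdict

AVOGADRO = 6.02214076e23  # 1/mol
POPC_MOLAR_MASS_G_MOL = 760.08
AREA_PER_LIPID_NM2 = 0.65
#: 25 ul standard addition vs 2 ul sample in 23 ul water
ASSAY_GEOMETRY_FACTOR = 12.5
#: relative agreement demanded between the compact and step-by-step chains
_CHAIN_CONSISTENCY_RTOL = 1e-12


def lipids_per_vesicle(
    diameter_nm: float, area_per_lipid_nm2: float = AREA_PER_LIPID_NM2
) -> float:
    """Number of lipids in both leaflets of a spherical vesicle.

    ``2 * pi * d^2 / a`` — kept as a real number (never rounded) so that
    downstream concentrations are exact functions of the inputs.
    """
    if diameter_nm <= 0 or area_per_lipid_nm2 <= 0:
        raise TitrationError("diameter and area per lipid must be positive")
    return 2.0 * math.pi * diameter_nm**2 / area_per_lipid_nm2


@dataclass(frozen=True)
class VesicleGeometry:
    """Mean vesicle diameter (from DLS/NTA/AFM) and headgroup area."""

    mean_diameter_nm: float
    area_per_lipid_nm2: float = AREA_PER_LIPID_NM2

    def __post_init__(self) -> None:
        lipids_per_vesicle(self.mean_diameter_nm, self.area_per_lipid_nm2)  # validates

    @property
    def lipids_per_vesicle(self) -> float:
        return lipids_per_vesicle(self.mean_diameter_nm, self.area_per_lipid_nm2)


def back_scale_concentration(
    lipid_conc_well_mg_ml: float,
    pre_dilution_factor: float = 1.0,
    assay_geometry_factor: float = ASSAY_GEOMETRY_FACTOR,
) -> float:
    """Standard-equivalent in-well readout -> original sample concentration.

    Multiplies by the assay geometry factor (12.5 = 25 ul / 2 ul, because
    the calibration abscissa is the concentration of the full 25-ul
    standard addition while a sample contributes only 2 ul of it) and by
    the operator's pre-dilution factor.
    """
    if pre_dilution_factor < 1 or assay_geometry_factor < 1:
        raise TitrationError("dilution and geometry factors must be >= 1")
    return lipid_conc_well_mg_ml * assay_geometry_factor * pre_dilution_factor


@dataclass(frozen=True)
class TitrationResult:
    """Full stoichiometric conversion record for one sample."""

    sample_id: str
    lipid_conc_well_mg_ml: float  # standard-equivalent readout
    lipid_conc_sample_mg_ml: float  # after back-scaling
    lipid_molar_mass_g_mol: float
    popc_molarity: float  # mol/L of lipid
    lipids_per_liter: float
    ev_per_liter: float
    ev_molarity: float  # mol/L of vesicles
    particles_per_ml: float
    geometry: VesicleGeometry
    dilution_chain: tuple[float, ...] = ()
    avogadro: float = AVOGADRO
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_id,
            "lipid_conc_well_mg_ml": self.lipid_conc_well_mg_ml,
            "lipid_mg_ml": self.lipid_conc_sample_mg_ml,
            "d_nm": self.geometry.mean_diameter_nm,
            "a_nm2": self.geometry.area_per_lipid_nm2,
            "N_l": self.geometry.lipids_per_vesicle,
            "popc_molar_mass_g_mol": self.lipid_molar_mass_g_mol,
            "popc_molarity_M": self.popc_molarity,
            "lipids_per_liter": self.lipids_per_liter,
            "ev_per_liter": self.ev_per_liter,
            "EV_molarity_M": self.ev_molarity,
            "particles_per_ml": self.particles_per_ml,
            "dilution_chain": list(self.dilution_chain),
            "flags": list(self.flags),
        }


def titrate(
    lipid_conc_sample_mg_ml: float,
    geometry: VesicleGeometry,
    lipid_molar_mass_g_mol: float = POPC_MOLAR_MASS_G_MOL,
    sample_id: str = "",
    lipid_conc_well_mg_ml: float | None = None,
    dilution_chain: tuple[float, ...] = (),
    flags: tuple[str, ...] = (),
) -> TitrationResult:
    """Convert a lipid mass concentration into vesicle molarity and count.

    Concentrations are carried in g/L internally (1 mg/ml = 1 g/L); the
    step-by-step chain (molarity -> molecules/L -> vesicles/L -> vesicle
    molarity) is computed alongside the compact single-expression form and
    the two must agree to a relative 1e-12.
    """
    if lipid_molar_mass_g_mol <= 0:
        raise TitrationError("lipid molar mass must be positive")
    if lipid_conc_sample_mg_ml < 0:
        raise TitrationError("lipid concentration must be non-negative")
    n_l = geometry.lipids_per_vesicle
    l_g_per_l = lipid_conc_sample_mg_ml  # 1 mg/ml == 1 g/L

    popc_molarity = l_g_per_l / lipid_molar_mass_g_mol
    lipids_per_liter = popc_molarity * AVOGADRO
    ev_per_liter = lipids_per_liter / n_l
    ev_molarity = ev_per_liter / AVOGADRO

    compact = l_g_per_l / (lipid_molar_mass_g_mol * n_l)
    if ev_molarity != 0 and abs(ev_molarity - compact) > _CHAIN_CONSISTENCY_RTOL * abs(compact):
        raise TitrationError("internal inconsistency between stoichiometric chains")

    return TitrationResult(
        sample_id=sample_id,
        lipid_conc_well_mg_ml=(
            lipid_conc_sample_mg_ml if lipid_conc_well_mg_ml is None else lipid_conc_well_mg_ml
        ),
        lipid_conc_sample_mg_ml=lipid_conc_sample_mg_ml,
        lipid_molar_mass_g_mol=lipid_molar_mass_g_mol,
        popc_molarity=popc_molarity,
        lipids_per_liter=lipids_per_liter,
        ev_per_liter=ev_per_liter,
        ev_molarity=ev_molarity,
        particles_per_ml=ev_per_liter / 1000.0,
        geometry=geometry,
        dilution_chain=dilution_chain,
        flags=flags,
    )


def particles_in_volume(result: TitrationResult, volume_ml: float) -> float:
    """Vesicle count in an arbitrary volume."""
    if volume_ml < 0:
        raise TitrationError("volume must be non-negative")
    return result.particles_per_ml * volume_ml


def particles_per_ml_to_molarity(particles_per_ml: float) -> float:
    """Particle-number concentration [1/ml] -> molarity [mol/L]."""
    return particles_per_ml * 1000.0 / AVOGADRO


def molarity_to_particles_per_ml(molarity: float) -> float:
    """Molarity [mol/L] -> particle-number concentration [1/ml]."""
    return molarity * AVOGADRO / 1000.0


def titrate_sample(
    verdict: PurityVerdict,
    model: CalibrationModel,
    geometry: VesicleGeometry,
    lipid_molar_mass_g_mol: float = POPC_MOLAR_MASS_G_MOL,
    assay_geometry_factor: float = ASSAY_GEOMETRY_FACTOR,
    plate_batch_id: str | None = None,
) -> TitrationResult:
    """Quantify a graded sample: gatekeeper + inversion + back-scaling.

    Refuses anything but a pure verdict (CASE 1 or CASE 2) with a
    quantification point — a reliable titration can be performed only on
    pure preparations.
    """
    if verdict.verdict not in PURE_VERDICTS or verdict.quantification_point is None:
        raise TitrationRefusedError(
            f"sample {verdict.sample_id!r} graded {verdict.verdict.value}: "
            "plasmonic titration cannot be performed on non-pure preparations"
        )
    check_batch(model, plate_batch_id)
    point = verdict.quantification_point
    well_conc = invert_calibration(model, point.ai_ratio_percent)
    sample_conc = back_scale_concentration(
        well_conc, point.dilution_factor, assay_geometry_factor
    )
    return titrate(
        sample_conc,
        geometry,
        lipid_molar_mass_g_mol,
        sample_id=verdict.sample_id,
        lipid_conc_well_mg_ml=well_conc,
        dilution_chain=(assay_geometry_factor, point.dilution_factor),
        flags=verdict.evidence,
    )
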