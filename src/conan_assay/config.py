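"""Run configuration: every threshold and constant, echoed into reports.

All numbers that shape a verdict or a titration are collected here so a
report is reproducible from its own provenance block: the grading
thresholds, the physical constants, the red-wavelength preference and the
effective optical path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .plasmonics import (
    DEFAULT_PATH_LENGTH_CM,
    HAISS_B1,
    HAISS_B2,
    HAISS_C1,
    HAISS_C2,
    HAISS_C3,
    HAISS_C4,
)
from .purity import PurityConfig
from .titration import (
    AREA_PER_LIPID_NM2,
    ASSAY_GEOMETRY_FACTOR,
    AVOGADRO,
    POPC_MOLAR_MASS_G_MOL,
)


@dataclass(frozen=True)
class RunConfig:
    """Bundle of thresholds and constants for a pipeline run."""

    purity: PurityConfig = field(default_factory=PurityConfig)
    red2: str | float = "auto"  # 850 | 800 | 780 | "auto"
    statistic_level: str = "index"  # replicate aggregation level
    area_per_lipid_nm2: float = AREA_PER_LIPID_NM2
    popc_molar_mass_g_mol: float = POPC_MOLAR_MASS_G_MOL
    assay_geometry_factor: float = ASSAY_GEOMETRY_FACTOR
    path_length_cm: float = DEFAULT_PATH_LENGTH_CM
    smooth_window: int | None = None  # odd 5..11 enables peak smoothing

    def to_dict(self) -> dict:
        return {
            "thresholds": self.purity.to_dict(),
            "red2": self.red2,
            "statistic_level": self.statistic_level,
            "constants": {
                "area_per_lipid_nm2": self.area_per_lipid_nm2,
                "popc_molar_mass_g_mol": self.popc_molar_mass_g_mol,
                "assay_geometry_factor": self.assay_geometry_factor,
                "path_length_cm": self.path_length_cm,
                "avogadro": AVOGADRO,
                "haiss": [HAISS_B1, HAISS_B2, HAISS_C1, HAISS_C2, HAISS_C3, HAISS_C4],
            },
            "smooth_window": self.smooth_window,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = raw.get("thresholds", {})
        purity = PurityConfig(
            **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in thresholds.items()
                if v is not None or k == "calibration_ai_range_percent"
            }
        )
        kwargs = {}
        for key in ("red2", "statistic_level", "smooth_window"):
            if key in raw:
                kwargs[key] = raw[key]
        consts = raw.get("constants", {})
        for key in ("area_per_lipid_nm2", "popc_molar_mass_g_mol",
                    "assay_geometry_factor", "path_length_cm"):
            if key in consts:
                kwargs[key] = consts[key]
        return cls(purity=purity, **kwargs)
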