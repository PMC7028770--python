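"""Shared fixtures: tiny synthetic plates and spectra built in memory."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from conan_assay.spectra import LayoutEntry, PlateLayout, PlateSpectra, Role, Spectrum
from conan_assay.synth import Scenario, ScenarioKind, SpectralModel, generate_plate

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

GRID = np.arange(400.0, 901.0, 1.0)


def gaussian_spectrum(
    center: float = 519.0,
    width: float = 30.0,
    height: float = 1.0,
    baseline: float = 0.0,
    well_id: str = "W",
    grid: np.ndarray = GRID,
) -> Spectrum:
    a = baseline + height * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
    return Spectrum(wavelengths_nm=grid.copy(), absorbances_au=a, well_id=well_id)


def flat_spectrum(level: float, well_id: str = "W", grid: np.ndarray = GRID) -> Spectrum:
    return Spectrum(grid.copy(), np.full(grid.size, float(level)), well_id=well_id)


@pytest.fixture(scope="session")
def clean_pure_plate():
    """Noise-free PURE scenario plate (standards + references + sample)."""
    return generate_plate(Scenario(kind=ScenarioKind.PURE, seed=11), with_noise=False)


@pytest.fixture(scope="session")
def clean_calibration_plate():
    return generate_plate(
        Scenario(kind=ScenarioKind.CALIBRATION, seed=12), with_noise=False
    )


@pytest.fixture
def tiny_layout() -> PlateLayout:
    return PlateLayout(
        entries=(
            LayoutEntry("A1", Role.BLANK),
            LayoutEntry("A2", Role.NORM_REF),
            LayoutEntry("A3", Role.INT_REF),
        )
    )


@pytest.fixture
def tiny_plate(tiny_layout) -> PlateSpectra:
    spectra = {
        "A1": flat_spectrum(0.05, "A1"),
        "A2": gaussian_spectrum(baseline=0.05, well_id="A2"),
        "A3": gaussian_spectrum(height=0.5, baseline=0.05, well_id="A3"),
    }
    return PlateSpectra(layout=tiny_layout, spectra=spectra, blank_corrected=False)
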