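"""Spectra I/O, blank correction and replicate grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conan_assay.errors import LayoutError, SpectrumError
from conan_assay.spectra import (
    LayoutEntry,
    PlateLayout,
    PlateSpectra,
    Role,
    Spectrum,
    aggregate_replicates,
    read_plate,
    read_spectra_csv,
    subtract_blank,
    summarize_values,
    write_long_csv,
)
from tests.conftest import GRID, flat_spectrum, gaussian_spectrum


class TestSpectrum:
    def test_validates_shape_monotonicity_and_length(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([500.0]), np.array([1.0]))
        with pytest.raises(SpectrumError):
            Spectrum(np.array([500.0, 499.0]), np.array([1.0, 1.0]))
        with pytest.raises(SpectrumError):
            Spectrum(np.array([500.0, 501.0]), np.array([1.0]))

    def test_interpolates_off_grid_wavelengths(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.0, 1.0]))
        assert s.absorbance_at(450.0) == pytest.approx(0.5)
        with pytest.raises(SpectrumError):
            s.absorbance_at(399.0)


def _write_layout(path, rows, batch=None):
    import yaml

    payload = {"wells": rows}
    if batch:
        payload["aunp_batch_id"] = batch
    path.write_text(yaml.safe_dump(payload))


LAYOUT_ROWS = [
    {"well": "A1", "role": "BLANK"},
    {"well": "A2", "role": "normREF"},
    {"well": "A3", "role": "intREF"},
]


class TestReadPlate:
    def _long_df(self, wells=("A1", "A2", "A3")):
        rng = np.random.default_rng(0)
        frames = []
        for w in wells:
            frames.append(
                pd.DataFrame(
                    {"well": w, "wavelength_nm": GRID,
                     "absorbance": rng.uniform(0, 1, GRID.size)}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_long_format_roundtrip_structure(self, tmp_path):
        df = self._long_df()
        f = tmp_path / "plate.csv"
        df.to_csv(f, index=False)
        lay = tmp_path / "layout.yaml"
        _write_layout(lay, LAYOUT_ROWS)
        plate = read_plate(f, lay)
        assert len(plate.spectra) == 3
        assert all(s.wavelengths_nm.size == 501 for s in plate.spectra.values())
        assert not plate.blank_corrected

    def test_wide_format_equivalent_to_long(self, tmp_path):
        df = self._long_df()
        long_f = tmp_path / "long.csv"
        df.to_csv(long_f, index=False)
        wide = df.pivot(index="wavelength_nm", columns="well", values="absorbance")
        wide_f = tmp_path / "wide.csv"
        wide.reset_index().to_csv(wide_f, index=False)
        lay = tmp_path / "layout.yaml"
        _write_layout(lay, LAYOUT_ROWS)
        assert read_plate(long_f, lay) == read_plate(wide_f, lay)

    def test_missing_well_is_an_error(self, tmp_path):
        df = self._long_df(wells=("A1", "A2"))
        f = tmp_path / "plate.csv"
        df.to_csv(f, index=False)
        lay = tmp_path / "layout.yaml"
        _write_layout(lay, LAYOUT_ROWS)
        with pytest.raises(LayoutError, match="missing spectrum.*A3"):
            read_plate(f, lay)

    def test_insufficient_coverage_rejected(self, tmp_path):
        grid = np.arange(500.0, 801.0, 1.0)  # misses 450-500
        frames = [
            pd.DataFrame({"well": w, "wavelength_nm": grid, "absorbance": 0.1})
            for w in ("A1", "A2", "A3")
        ]
        f = tmp_path / "plate.csv"
        pd.concat(frames).to_csv(f, index=False)
        lay = tmp_path / "layout.yaml"
        _write_layout(lay, LAYOUT_ROWS)
        with pytest.raises(SpectrumError, match="coverage"):
            read_plate(f, lay)

    def test_write_read_idempotent(self, tmp_path, clean_pure_plate):
        plate = clean_pure_plate.plate
        f1 = tmp_path / "a.csv"
        write_long_csv(plate, f1)
        spectra1 = read_spectra_csv(f1)
        p1 = PlateSpectra(plate.layout, spectra1, blank_corrected=False)
        f2 = tmp_path / "b.csv"
        write_long_csv(p1, f2)
        assert f1.read_text() == f2.read_text()


class TestLayout:
    def test_requires_all_three_reference_roles(self):
        with pytest.raises(LayoutError, match="BLANK"):
            PlateLayout(entries=(LayoutEntry("A1", Role.NORM_REF),
                                 LayoutEntry("A2", Role.INT_REF)))
        with pytest.raises(LayoutError, match="normREF"):
            PlateLayout(entries=(LayoutEntry("A1", Role.BLANK),
                                 LayoutEntry("A2", Role.INT_REF)))

    def test_rejects_duplicates_and_bad_parameters(self):
        base = (LayoutEntry("A1", Role.BLANK), LayoutEntry("A2", Role.NORM_REF),
                LayoutEntry("A3", Role.INT_REF))
        with pytest.raises(LayoutError, match="duplicate"):
            PlateLayout(entries=base + (LayoutEntry("A1", Role.BLANK),))
        with pytest.raises(LayoutError, match="positive"):
            PlateLayout(entries=base + (
                LayoutEntry("A4", Role.STANDARD, concentration_mg_per_ml=-1.0),))
        with pytest.raises(LayoutError, match="dilution_factor"):
            PlateLayout(entries=base + (
                LayoutEntry("A4", Role.SAMPLE, sample_id="S", dilution_factor=0.5),))


class TestSubtractBlank:
    def test_well_equal_to_blank_corrects_to_zero(self, tiny_plate):
        plate = tiny_plate
        plate.spectra["A2"] = flat_spectrum(0.05, "A2")
        out = subtract_blank(plate)
        assert np.allclose(out.spectra["A2"].absorbances_au, 0.0)
        assert np.allclose(out.spectra["A1"].absorbances_au, 0.0)
        assert out.blank_corrected

    def test_constant_blank_shifts_every_wavelength(self, tiny_plate):
        out = subtract_blank(tiny_plate)
        expected = tiny_plate.spectra["A2"].absorbances_au - 0.05
        assert np.allclose(out.spectra["A2"].absorbances_au, expected)

    def test_multiple_blanks_subtract_their_mean(self):
        layout = PlateLayout(entries=(
            LayoutEntry("A1", Role.BLANK), LayoutEntry("A2", Role.BLANK),
            LayoutEntry("A3", Role.NORM_REF), LayoutEntry("A4", Role.INT_REF)))
        spectra = {
            "A1": flat_spectrum(0.04, "A1"), "A2": flat_spectrum(0.06, "A2"),
            "A3": gaussian_spectrum(baseline=0.05, well_id="A3"),
            "A4": gaussian_spectrum(height=0.5, baseline=0.05, well_id="A4"),
        }
        out = subtract_blank(PlateSpectra(layout, spectra))
        # oracle: arithmetic mean of the two flat blanks is 0.05
        expected = spectra["A3"].absorbances_au - 0.05
        assert np.allclose(out.spectra["A3"].absorbances_au, expected)

    def test_double_correction_rejected(self, tiny_plate):
        out = subtract_blank(tiny_plate)
        with pytest.raises(SpectrumError, match="already"):
            subtract_blank(out)

    @given(st.floats(min_value=0.0, max_value=0.5))
    def test_linearity_recovers_sample_exactly(self, blank_level):
        """Subtracting the blank from (sample + blank) gives back the sample."""
        layout = PlateLayout(entries=(
            LayoutEntry("A1", Role.BLANK), LayoutEntry("A2", Role.NORM_REF),
            LayoutEntry("A3", Role.INT_REF)))
        sample = gaussian_spectrum(well_id="A2")
        spectra = {
            "A1": flat_spectrum(blank_level, "A1"),
            "A2": Spectrum(GRID.copy(), sample.absorbances_au + blank_level, "A2"),
            "A3": flat_spectrum(blank_level + 0.5, "A3"),
        }
        out = subtract_blank(PlateSpectra(layout, spectra))
        assert np.allclose(out.spectra["A2"].absorbances_au, sample.absorbances_au)


class TestReplicates:
    def test_index_level_mean_and_sd(self):
        stats = summarize_values([2.0, 2.2, 2.4])
        assert stats.mean == pytest.approx(2.2)
        assert stats.sd == pytest.approx(0.2)
        assert stats.n == 3 and stats.flags == ()

    def test_single_well_group_flagged(self):
        stats = summarize_values([3.3])
        assert stats.mean == 3.3 and stats.sd == 0.0
        assert "single_replicate" in stats.flags

    def test_high_scatter_flagged_above_cv_threshold(self):
        assert "high_replicate_scatter" in summarize_values([1.0, 1.5, 2.0]).flags
        assert summarize_values([1.0, 1.01, 0.99]).flags == ()

    def test_spectrum_level_averages_pointwise(self, clean_pure_plate):
        plate = subtract_blank(clean_pure_plate.plate)
        groups_idx = aggregate_replicates(plate, "index")
        groups_spec = aggregate_replicates(plate, "spectrum")
        g = next(k for k in groups_idx if k.startswith("std-"))
        members = groups_idx[g]
        mean = np.mean([m.absorbances_au for m in members], axis=0)
        assert np.allclose(groups_spec[g].absorbances_au, mean)

    def test_uncorrected_plate_rejected(self, tiny_plate):
        with pytest.raises(SpectrumError, match="blank-corrected"):
            aggregate_replicates(tiny_plate)
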