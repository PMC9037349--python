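"""Spectrum/series containers and the plain-text round trip."""

import numpy as np
import pytest

from specbind import (Spectrum, SpectrumKind, TitrationPoint, TitrationSeries,
                      read_spectrum, read_titration, write_spectrum,
                      write_titration)
from specbind.simulate import GeneratorSpec, generate_titration

from conftest import make_emission


class TestSpectrumInvariants:
    def test_minimal_spectrum(self):
        s = Spectrum([290.0, 335.0, 450.0], [0.0, 100.0, 0.0])
        assert s.peak_wavelength_nm == 335.0
        assert s.value_at(335.0) == 100.0

    @pytest.mark.parametrize("wl,vals,msg", [
        ([335.0], [1.0], "at least 2"),
        ([290.0, 290.0, 450.0], [1.0, 2.0, 3.0], "duplicate wavelength"),
        ([450.0, 290.0], [1.0, 2.0], "strictly increasing"),
        ([290.0, 450.0], [1.0, 2.0, 3.0], "length"),
        ([290.0, 450.0], [1.0, -2.0], ">= 0"),
    ])
    def test_invalid_spectra_rejected(self, wl, vals, msg):
        with pytest.raises(ValueError, match=msg):
            Spectrum(wl, vals, SpectrumKind.EMISSION)

    def test_interpolation_is_linear_between_grid_points(self):
        s = Spectrum([200.0, 210.0], [0.0, 10.0], SpectrumKind.ELLIPTICITY)
        assert s.value_at(208.0) == pytest.approx(8.0)

    def test_value_outside_grid_raises(self):
        s = Spectrum([290.0, 450.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="outside"):
            s.value_at(260.0)


class TestSpectrumFiles:
    def test_read_two_column_csv(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("290,0.0\n335,100.0\n450,0.0\n")
        s = read_spectrum(p)
        assert s.wavelengths_nm.tolist() == [290.0, 335.0, 450.0]
        assert s.value_at(335.0) == 100.0

    def test_header_and_tab_delimiter_accepted(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("wavelength_nm\tvalue\n290\t1.5\n450\t2.5\n")
        s = read_spectrum(p, SpectrumKind.ABSORBANCE)
        assert s.values.tolist() == [1.5, 2.5]

    def test_unsorted_rows_are_sorted_with_warning(self, tmp_path, caplog):
        p = tmp_path / "s.csv"
        p.write_text("450,0.0\n290,1.0\n335,2.0\n")
        with caplog.at_level("WARNING", logger="specbind"):
            s = read_spectrum(p)
        assert "sorting" in caplog.text
        assert np.all(np.diff(s.wavelengths_nm) > 0)

    def test_duplicate_wavelength_row_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("290,1.0\n290,2.0\n450,0.0\n")
        with pytest.raises(ValueError, match="duplicate wavelength"):
            read_spectrum(p)

    def test_non_numeric_row_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("290,1.0\n335,abc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_spectrum(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_spectrum(tmp_path / "nope.csv")

    def test_write_read_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        wl = np.sort(rng.uniform(200, 700, 50))
        s = Spectrum(wl, rng.uniform(0, 1e3, 50), SpectrumKind.EMISSION, "rt")
        s2 = read_spectrum(write_spectrum(s, tmp_path / "rt.csv"))
        np.testing.assert_array_equal(s.wavelengths_nm, s2.wavelengths_nm)
        np.testing.assert_array_equal(s.values, s2.values)


class TestTitrationSeries:
    def test_points_sorted_and_reference_is_zero(self):
        pts = [TitrationPoint(c, make_emission(100 - i))
               for i, c in enumerate([1e-5, 0.0, 5e-6])]
        series = TitrationSeries(tuple(pts), 298.0, 280.0, 5e-6)
        assert series.points[0].quencher_conc_M == 0.0
        assert list(series.concentrations_M) == [0.0, 5e-6, 1e-5]

    def test_missing_zero_point_rejected(self):
        pts = [TitrationPoint(c, make_emission(1.0)) for c in (1e-6, 2e-6, 3e-6)]
        with pytest.raises(ValueError, match="zero-concentration"):
            TitrationSeries(tuple(pts), 298.0, 280.0, 5e-6)

    def test_mismatched_grids_rejected(self):
        a = TitrationPoint(0.0, make_emission(1.0))
        b = TitrationPoint(1e-6, make_emission(1.0))
        shifted = Spectrum([291.0, 335.0, 450.0], [0.1, 1.0, 0.1])
        c = TitrationPoint(2e-6, shifted)
        with pytest.raises(ValueError, match="grid"):
            TitrationSeries((a, b, c), 298.0, 280.0, 5e-6)


class TestManifests:
    def test_manifest_round_trip(self, tmp_path):
        series = generate_titration(GeneratorSpec(noise_cv=0.01, seed=3), 298.0)
        manifest = write_titration(series, tmp_path, name="t298")
        back = read_titration(manifest)
        assert back.temperature_K == series.temperature_K
        assert back.protein_conc_M == series.protein_conc_M
        for p, q in zip(series.points, back.points):
            assert p.quencher_conc_M == q.quencher_conc_M
            np.testing.assert_array_equal(p.spectrum.values, q.spectrum.values)

    def test_micromolar_manifest_converted(self, tmp_path):
        for i, c in enumerate([0, 5, 10]):
            (tmp_path / f"p{i}.csv").write_text("290,1\n335,10\n450,1\n")
        (tmp_path / "m.yaml").write_text(
            "temperature_K: 298\nexcitation_nm: 280\nprotein_conc_M: 5e-6\n"
            "conc_unit: uM\npoints:\n"
            "  - {conc: 0, file: p0.csv}\n"
            "  - {conc: 5, file: p1.csv}\n"
            "  - {conc: 10, file: p2.csv}\n")
        series = read_titration(tmp_path / "m.yaml")
        assert series.concentrations_M.tolist() == [0.0, 5e-6, 1e-5]

    def test_manifest_without_zero_point_rejected(self, tmp_path):
        for i in range(3):
            (tmp_path / f"p{i}.csv").write_text("290,1\n335,10\n450,1\n")
        (tmp_path / "m.yaml").write_text(
            "temperature_K: 298\nexcitation_nm: 280\nprotein_conc_M: 5e-6\n"
            "points:\n  - {conc: 1e-6, file: p0.csv}\n"
            "  - {conc: 2e-6, file: p1.csv}\n  - {conc: 3e-6, file: p2.csv}\n")
        with pytest.raises(ValueError, match="zero-concentration"):
            read_titration(tmp_path / "m.yaml")

    def test_offending_grid_named(self, tmp_path):
        (tmp_path / "p0.csv").write_text("290,1\n335,10\n450,1\n")
        (tmp_path / "p1.csv").write_text("290,1\n335,10\n450,1\n")
        (tmp_path / "bad.csv").write_text("290,1\n336,10\n450,1\n")
        (tmp_path / "m.yaml").write_text(
            "temperature_K: 298\nexcitation_nm: 280\nprotein_conc_M: 5e-6\n"
            "points:\n  - {conc: 0, file: p0.csv}\n"
            "  - {conc: 1e-6, file: p1.csv}\n  - {conc: 2e-6, file: bad.csv}\n")
        with pytest.raises(ValueError, match="bad.csv"):
            read_titration(tmp_path / "m.yaml")
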