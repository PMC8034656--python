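import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doxorigami.errors import DomainError, ParseError, ValidationError
from doxorigami.spectra import (
    FreeDoxReference,
    Spectrum,
    integrate_emission,
    quantum_yield_proxy,
    read_spectrum_csv,
    subtract_reference,
    subtract_scatter_baseline,
    transmittance,
    write_spectrum_csv,
)


def make_spectrum(wl, vals, kind="absorbance", **kw):
    return Spectrum(np.asarray(wl, float), np.asarray(vals, float), kind=kind, **kw)


class TestSpectrumInvariants:
    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValidationError):
            make_spectrum([400, 500], [1.0])

    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValidationError):
            make_spectrum([500, 480, 520], [1, 2, 3])

    def test_rejects_single_point(self):
        with pytest.raises(ValidationError):
            make_spectrum([400], [1.0])

    def test_rejects_nonfinite_values(self):
        with pytest.raises(ValidationError):
            make_spectrum([400, 500], [1.0, np.nan])

    def test_value_at_interpolates(self):
        s = make_spectrum([400, 500], [0.0, 1.0])
        assert s.value_at(450) == pytest.approx(0.5)
        with pytest.raises(DomainError):
            s.value_at(600)


class TestSpectrumCsv:
    def test_roundtrip_with_excitation_header(self, tmp_path):
        path = tmp_path / "em.csv"
        s = make_spectrum([500, 550, 600], [1.0, 2.0, 1.5], kind="emission",
                          excitation_nm=494.0)
        write_spectrum_csv(s, path)
        back = read_spectrum_csv(path, kind="emission")
        assert back.excitation_nm == 494.0
        np.testing.assert_allclose(back.wavelengths_nm, s.wavelengths_nm)
        np.testing.assert_allclose(back.values, s.values)

    def test_three_row_csv(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("wavelength_nm,value\n400,0.1\n500,0.2\n600,0.3\n")
        s = read_spectrum_csv(path, kind="absorbance")
        assert s.wavelengths_nm.size == 3

    def test_duplicate_wavelength_is_parse_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("480,0.1\n480,0.2\n500,0.3\n")
        with pytest.raises(ParseError, match="duplicate wavelength 480"):
            read_spectrum_csv(path, kind="absorbance")

    def test_unsorted_rows_sorted_with_warning(self, tmp_path):
        path = tmp_path / "unsorted.csv"
        path.write_text("500,0.2\n480,0.1\n520,0.3\n")
        with pytest.warns(UserWarning, match="not sorted"):
            s = read_spectrum_csv(path, kind="absorbance")
        np.testing.assert_array_equal(s.wavelengths_nm, [480, 500, 520])
        np.testing.assert_allclose(s.values, [0.1, 0.2, 0.3])

    def test_non_numeric_cell_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("400,0.1\n500,abc\n")
        with pytest.raises(ParseError, match=":2"):
            read_spectrum_csv(path, kind="absorbance")

    def test_wrong_column_count(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("400,0.1,9\n500,0.2,9\n")
        with pytest.raises(ParseError, match="expected 2 columns"):
            read_spectrum_csv(path, kind="absorbance")


class TestTransmittanceAndProxy:
    @pytest.mark.parametrize("absorbance,expected", [(0.0, 1.0), (1.0, 0.1), (2.0, 0.01)])
    def test_transmittance_definition(self, absorbance, expected):
        assert transmittance(absorbance) == pytest.approx(expected)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(DomainError):
            transmittance(-0.1)

    @given(st.floats(min_value=0.0, max_value=5.0), st.floats(min_value=1e-3, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_transmittance_strictly_decreasing(self, a, da):
        assert transmittance(a + da) < transmittance(a)

    def test_proxy_arithmetic(self):
        # A = 1 -> T = 0.1 -> absorbed fraction 0.9
        assert quantum_yield_proxy(1.0, 1.0) == pytest.approx(1.0 / 0.9)
        assert quantum_yield_proxy(0.0, 0.5) == 0.0
        assert quantum_yield_proxy(5.0, 50.0) == pytest.approx(5.0)  # all light absorbed

    def test_proxy_zero_absorbance_raises(self):
        with pytest.raises(DomainError, match="no light is absorbed"):
            quantum_yield_proxy(1.0, 0.0)

    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=0.01, max_value=3.0),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_proxy_homogeneous_in_emission(self, intensity, absorbance, k):
        lhs = quantum_yield_proxy(k * intensity, absorbance)
        rhs = k * quantum_yield_proxy(intensity, absorbance)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestIntegrateEmission:
    def test_constant_rectangle(self):
        s = make_spectrum(np.linspace(500, 600, 11), np.full(11, 2.0), kind="emission")
        assert integrate_emission(s, 500, 600) == pytest.approx(200.0)

    def test_zero_spectrum(self):
        s = make_spectrum(np.linspace(500, 600, 11), np.zeros(11), kind="emission")
        assert integrate_emission(s, 500, 600) == 0.0

    def test_triangular_peak(self):
        wl = np.array([500.0, 550.0, 600.0])
        s = make_spectrum(wl, [0.0, 1.0, 0.0], kind="emission")
        assert integrate_emission(s, 500, 600) == pytest.approx(50.0)

    def test_no_overlap_raises(self):
        s = make_spectrum([500, 600], [1, 1], kind="emission")
        with pytest.raises(DomainError, match="does not overlap"):
            integrate_emission(s, 700, 800)

    def test_absorbance_rejected(self):
        s = make_spectrum([500, 600], [1, 1], kind="absorbance")
        with pytest.raises(DomainError):
            integrate_emission(s, 500, 600)

    @given(st.floats(min_value=505, max_value=595))
    @settings(max_examples=30, deadline=None)
    def test_additive_over_adjacent_intervals(self, split):
        rng = np.random.default_rng(42)
        wl = np.linspace(500, 600, 51)
        s = make_spectrum(wl, rng.uniform(0, 3, wl.size), kind="emission")
        whole = integrate_emission(s, 500, 600)
        parts = integrate_emission(s, 500, split) + integrate_emission(s, split, 600)
        assert parts == pytest.approx(whole, rel=1e-9)


class TestSubtractReference:
    def test_self_subtraction_zero(self):
        s = make_spectrum([400, 500, 600], [0.3, 0.2, 0.1])
        out = subtract_reference(s, s, scale=1.0)
        np.testing.assert_allclose(out.values, 0.0)

    def test_scale_zero_identity(self):
        s = make_spectrum([400, 500], [0.3, 0.2])
        r = make_spectrum([400, 500], [0.1, 0.1])
        np.testing.assert_allclose(subtract_reference(s, r, 0.0).values, s.values)

    def test_dox_a260_removal(self):
        sample = make_spectrum([250, 260, 270], [0.28, 0.30, 0.27])
        dox = make_spectrum([250, 260, 270], [0.04, 0.05, 0.04])
        corrected = subtract_reference(sample, dox)
        assert corrected.value_at(260) == pytest.approx(0.25)

    def test_disjoint_ranges_raise(self):
        s = make_spectrum([400, 500], [1, 1])
        r = make_spectrum([600, 700], [1, 1])
        with pytest.raises(DomainError, match="does not cover"):
            subtract_reference(s, r)


def test_scatter_baseline_subtracts_reference_wavelength():
    wl = np.array([260.0, 500.0, 700.0])
    s = make_spectrum(wl, [0.30, 0.12, 0.02])
    out = subtract_scatter_baseline(s, reference_nm=700.0)
    np.testing.assert_allclose(out.values, [0.28, 0.10, 0.0])


def test_free_dox_reference_validation():
    ref = FreeDoxReference(c_dox=3e-6, phi0_proxy=100.0, a260_dox=0.05)
    assert ref.c_dox == 3e-6
    with pytest.raises(ValidationError):
        FreeDoxReference(c_dox=0.0, phi0_proxy=1.0)
    with pytest.raises(ValidationError):
        FreeDoxReference(c_dox=1e-6, phi0_proxy=-1.0)
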