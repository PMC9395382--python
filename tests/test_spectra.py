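import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyedna.spectra import (
    Spectrum,
    SpectrumParseError,
    bathochromic_shift,
    enhancement_ratio,
    fit_beer_lambert,
    integrate_band,
    lambda_max,
    read_spectrum,
    write_spectrum_csv,
)


def gaussian_band(center, fwhm=60.0, amplitude=1.0, grid=None, kind="absorption"):
    wl = np.arange(400.0, 800.5, 1.0) if grid is None else grid
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return Spectrum(wl, amplitude * np.exp(-0.5 * ((wl - center) / sigma) ** 2), kind)


class TestSpectrumInvariants:
    def test_rejects_short_unsorted_or_mismatched(self):
        with pytest.raises(ValueError):
            Spectrum([500, 510], [1, 2], "absorption")
        with pytest.raises(ValueError):
            Spectrum([500, 520, 510], [1, 2, 3], "emission")
        with pytest.raises(ValueError):
            Spectrum([500, 510, 520], [1, 2], "absorption")
        with pytest.raises(ValueError):
            Spectrum([500, 510, 520], [1, 2, 3], "luminescence")

    def test_absorbance_baseline_tolerance(self):
        Spectrum([500, 510, 520], [0.1, -0.005, 0.1], "absorption")
        with pytest.raises(ValueError, match="baseline"):
            Spectrum([500, 510, 520], [0.1, -0.5, 0.1], "absorption")


class TestReadSpectrum:
    def test_parses_three_row_csv(self):
        s = read_spectrum(io.StringIO("500,0.1\n510,0.2\n520,0.1"), kind="absorption")
        assert len(s) == 3
        assert s.values[1] == 0.2

    def test_header_and_tabs_accepted(self):
        s = read_spectrum(
            io.StringIO("wavelength_nm\tvalue\n500\t0.1\n510\t0.2\n520\t0.1"),
            kind="emission",
            meta={"dye": "x"},
        )
        assert s.meta["dye"] == "x"

    def test_duplicate_wavelength_rejected(self):
        with pytest.raises(SpectrumParseError, match="duplicate"):
            read_spectrum(
                io.StringIO("500,0.1\n510,0.2\n510,0.3\n520,0.1"), kind="absorption"
            )

    def test_unsorted_rows_equal_sorted(self):
        a = read_spectrum(io.StringIO("520,0.1\n500,0.3\n510,0.2"), kind="absorption")
        b = read_spectrum(io.StringIO("500,0.3\n510,0.2\n520,0.1"), kind="absorption")
        np.testing.assert_array_equal(a.wavelengths_nm, b.wavelengths_nm)
        np.testing.assert_array_equal(a.values, b.values)

    def test_malformed_row_names_line(self):
        with pytest.raises(SpectrumParseError, match=":3"):
            read_spectrum(io.StringIO("500,0.1\n510,0.2\nbogus\n520,0.1"), kind="absorption")

    def test_round_trip_through_csv(self, tmp_path):
        s = gaussian_band(547.0)
        path = tmp_path / "band.csv"
        write_spectrum_csv(s, path)
        back = read_spectrum(path, kind="absorption")
        np.testing.assert_allclose(back.values, s.values, rtol=1e-9)


class TestLambdaMax:
    @pytest.mark.parametrize("center", [547.0, 595.0])
    def test_peak_of_gaussian_band(self, center):
        assert lambda_max(gaussian_band(center)) == center

    def test_tie_broken_to_longest_wavelength(self):
        s = Spectrum([490, 500, 510, 520, 530], [0, 1.0, 0.5, 1.0, 0], "absorption")
        assert lambda_max(s) == 520

    def test_window_restricts_search(self):
        s = Spectrum([490, 500, 510, 520, 530], [0, 1.0, 0.5, 0.8, 0], "absorption")
        assert lambda_max(s, window_nm=(505, 530)) == 520
        with pytest.raises(ValueError, match="window"):
            lambda_max(s, window_nm=(600, 650))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_positive_rescaling(self, scale):
        s = gaussian_band(611.0)
        scaled = Spectrum(s.wavelengths_nm, s.values * scale, s.kind)
        assert lambda_max(scaled) == lambda_max(s)


class TestBathochromicShift:
    def test_red_shift_of_bound_band(self):
        assert bathochromic_shift(gaussian_band(547), gaussian_band(595)) == 48
        assert bathochromic_shift(gaussian_band(528), gaussian_band(558)) == 30

    def test_identical_spectra_shift_zero(self):
        s = gaussian_band(547)
        assert bathochromic_shift(s, s) == 0

    def test_antisymmetry(self):
        a, b = gaussian_band(547), gaussian_band(595)
        assert bathochromic_shift(a, b) == -bathochromic_shift(b, a)

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            bathochromic_shift(
                gaussian_band(547), gaussian_band(595, kind="emission")
            )


class TestBeerLambert:
    def test_noiseless_slope_recovered_exactly(self):
        c = np.linspace(0, 10e-6, 6)
        fit = fit_beer_lambert(c, 5.0e4 * c, path_length_cm=1.0)
        np.testing.assert_allclose(fit.epsilon, 5.0e4, rtol=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_intercept_reported_as_baseline(self):
        c = np.linspace(0, 10e-6, 6)
        fit = fit_beer_lambert(c, 2.5e4 * c + 0.01)
        np.testing.assert_allclose(fit.epsilon, 2.5e4, rtol=1e-9)
        np.testing.assert_allclose(fit.intercept, 0.01, rtol=1e-9)

    def test_path_length_divides_slope(self):
        c = np.linspace(0, 10e-6, 6)
        fit = fit_beer_lambert(c, 5.0e4 * c, path_length_cm=0.5)
        np.testing.assert_allclose(fit.epsilon, 1.0e5, rtol=1e-9)

    def test_all_zero_absorbance_gives_zero_epsilon(self):
        c = np.linspace(0, 10e-6, 6)
        assert fit_beer_lambert(c, np.zeros_like(c)).epsilon == 0

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_beer_lambert([1e-6] * 5, [0.1] * 5)


class TestEnhancementRatio:
    @pytest.mark.parametrize(
        "F,F0,expected", [(1.0, 1.0, 1.0), (126.0, 1.0, 126.0), (3.5, 1.0, 3.5)]
    )
    def test_ratio(self, F, F0, expected):
        assert enhancement_ratio(F, F0) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            enhancement_ratio(1.0, 0.0)


class TestIntegrateBand:
    def test_constant_band_area(self):
        wl = np.linspace(500, 600, 201)
        s = Spectrum(wl, np.ones_like(wl), "emission")
        assert integrate_band(s) == pytest.approx(100.0)

    def test_unit_area_gaussian(self):
        wl = np.arange(400, 800.5, 0.5)
        sigma = 20.0
        vals = np.exp(-0.5 * ((wl - 600) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        s = Spectrum(wl, vals, "emission")
        assert integrate_band(s) == pytest.approx(1.0, abs=1e-3)

    def test_linearity_and_window_additivity(self):
        s = gaussian_band(600, grid=np.arange(400, 800.5, 0.5), kind="emission")
        doubled = Spectrum(s.wavelengths_nm, 2 * s.values, s.kind)
        assert integrate_band(doubled) == pytest.approx(2 * integrate_band(s))
        total = integrate_band(s, (400, 800))
        parts = integrate_band(s, (400, 600)) + integrate_band(s, (600, 800))
        assert parts == pytest.approx(total, rel=1e-12)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            integrate_band(gaussian_band(547), (900, 950))
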