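"""Gaussian convolution of stick spectra and ensemble weighting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemblecd.errors import DataError, FormatError, StructuralError
from ensemblecd.spectra import (
    EV_NM,
    ConvolvedSpectrum,
    Lineshape,
    Stick,
    StickSpectrum,
    combine_weighted,
    convolve,
    convolve_absorption,
    convolve_cd,
    default_grid,
    half_width_check,
    hwhm_from_sigma,
    read_sticks,
    sigma_from_hwhm,
    write_sticks,
)


@pytest.fixture
def rng():
    return np.random.default_rng(61)


@pytest.fixture
def fine_grid():
    return np.linspace(3.0, 9.0, 60001)  # 1e-4 eV step


def single(E=6.0, f=0.01, R=1.0, label="x"):
    return StickSpectrum(label=label, sticks=[Stick(E, f, R)])


class TestLineshape:
    def test_unit_sigma_case(self):
        """HWHM = sqrt(ln 2) gives sigma exactly 1."""
        assert sigma_from_hwhm(np.sqrt(np.log(2.0))) == pytest.approx(1.0, abs=1e-12)

    def test_hwhm_04_closed_form(self):
        # sigma solving exp(-(0.4/sigma)^2) = 1/2, evaluated independently
        independent = 0.4 / np.sqrt(-np.log(0.5))
        assert sigma_from_hwhm(0.4) == pytest.approx(independent, rel=1e-12)
        assert sigma_from_hwhm(0.4) == pytest.approx(0.480449, abs=5e-7)

    @settings(derandomize=True, max_examples=30)
    @given(h=st.floats(1e-3, 5.0))
    def test_round_trip(self, h):
        assert hwhm_from_sigma(sigma_from_hwhm(h)) == pytest.approx(h, rel=1e-12)

    def test_half_maximum_identity(self):
        """exp(-(HWHM/sigma)^2) = 1/2 by construction."""
        for h in (0.3, 0.4, 1.1):
            assert np.exp(-((h / sigma_from_hwhm(h)) ** 2)) == pytest.approx(0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sigma_from_hwhm(0.0)


class TestAbsorption:
    def test_empty_sticks_zero_spectrum(self, fine_grid):
        eps = convolve_absorption(StickSpectrum("e", []), Lineshape(0.4), fine_grid)
        assert np.all(eps == 0)

    def test_single_stick_peak_value(self, fine_grid):
        """f = 0.01 at 6 eV with sigma 0.480450: peak eps = 337.0 (closed form
        2.870e4 * f / (sigma sqrt(pi)) evaluated independently)."""
        eps = convolve_absorption(single(f=0.01), Lineshape(0.4), fine_grid)
        sigma = sigma_from_hwhm(0.4)
        independent = 2.870e4 * 0.01 / (sigma * np.sqrt(np.pi))
        assert eps.max() == pytest.approx(independent, rel=1e-8)
        assert eps.max() == pytest.approx(337.0, abs=0.05)

    def test_linearity_in_amplitudes(self, fine_grid):
        one = convolve_absorption(single(f=0.02), Lineshape(0.4), fine_grid)
        two = convolve_absorption(
            StickSpectrum("d", [Stick(6.0, 0.02, 0), Stick(6.0, 0.02, 0)]),
            Lineshape(0.4), fine_grid)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_integral_conserves_total_strength(self):
        """Integral of eps over a wide grid = 2.870e4 * sum f (Gaussian area)."""
        grid = np.linspace(0.0, 12.0, 120001)
        sticks = StickSpectrum("i", [Stick(5.0, 0.1, 0), Stick(6.5, 0.25, 0)])
        eps = convolve_absorption(sticks, Lineshape(0.4), grid)
        integral = np.trapezoid(eps, grid)
        assert integral == pytest.approx(2.870e4 * 0.35, rel=1e-6)

    def test_shift_equivariance(self, fine_grid):
        base = convolve_absorption(single(E=5.5, f=0.1), Lineshape(0.3), fine_grid)
        shifted = convolve_absorption(single(E=6.5, f=0.1), Lineshape(0.3), fine_grid)
        step = fine_grid[1] - fine_grid[0]
        k = int(round(1.0 / step))
        np.testing.assert_allclose(shifted[k:], base[:-k], rtol=1e-9, atol=1e-9)


class TestCircularDichroism:
    def test_zero_rotatory_zero_cd(self, fine_grid):
        deps = convolve_cd(single(R=0.0), Lineshape(0.4), fine_grid)
        assert np.all(deps == 0)

    def test_single_stick_peak_value(self, fine_grid):
        """R = 1e-40 cgs at 6 eV: peak Deps = 0.3067 (independent closed form
        (1e-40/2.297e-39) * E0 / (sigma sqrt(pi)))."""
        deps = convolve_cd(single(R=1.0), Lineshape(0.4), fine_grid)
        sigma = sigma_from_hwhm(0.4)
        independent = (1e-40 / 2.297e-39) * 6.0 / (sigma * np.sqrt(np.pi))
        assert deps.max() == pytest.approx(independent, rel=1e-8)
        assert deps.max() == pytest.approx(0.3067, abs=5e-5)

    def test_raw_cgs_units_flag(self, fine_grid):
        scaled = convolve_cd(single(R=1.0), Lineshape(0.4), fine_grid,
                             rotatory_units="1e-40cgs")
        raw = convolve_cd(single(R=1e-40), Lineshape(0.4), fine_grid,
                          rotatory_units="raw_cgs")
        np.testing.assert_allclose(scaled, raw, rtol=1e-12)

    def test_enantiomer_antisymmetry(self, fine_grid, rng):
        sticks = [Stick(float(e), float(f), float(r))
                  for e, f, r in zip(rng.uniform(5, 7, 10),
                                     rng.uniform(0, 0.2, 10),
                                     rng.normal(0, 5, 10))]
        mirrored = [Stick(s.energy, s.oscillator, -s.rotatory) for s in sticks]
        a = convolve_cd(StickSpectrum("a", sticks), Lineshape(0.3), fine_grid)
        b = convolve_cd(StickSpectrum("b", mirrored), Lineshape(0.3), fine_grid)
        np.testing.assert_allclose(b, -a, rtol=1e-12)


class TestHalfWidth:
    @pytest.mark.parametrize("hwhm", [0.4, 0.3])
    def test_realized_half_width_matches_configuration(self, hwhm):
        """The convolved single-stick band reproduces the configured HWHM."""
        grid = np.arange(3.0, 9.0, 1e-4)
        spectrum = convolve(single(f=1.0, R=0.0), Lineshape(hwhm), grid)
        assert half_width_check(spectrum) == pytest.approx(hwhm, abs=2e-4)

    def test_coarse_grid_raises(self):
        grid = np.linspace(5.9, 6.1, 5)  # cannot bracket the half maximum
        spectrum = convolve(single(f=1.0), Lineshape(0.4), grid)
        import ensemblecd.errors as err
        with pytest.raises(err.NumericalError):
            half_width_check(spectrum)


class TestCombine:
    def make_spectrum(self, grid, scale, label="s"):
        return ConvolvedSpectrum(energies=grid, epsilon=scale * np.ones_like(grid),
                                 delta_epsilon=scale * np.ones_like(grid), label=label)

    def test_equal_weights_identity(self, fine_grid):
        s = convolve(single(f=0.1, R=2.0), Lineshape(0.4), fine_grid)
        out = combine_weighted([s, s], [0.5, 0.5])
        np.testing.assert_allclose(out.epsilon, s.epsilon, rtol=1e-12)
        np.testing.assert_allclose(out.delta_epsilon, s.delta_epsilon, rtol=1e-12)

    def test_zero_weight_excludes(self, fine_grid):
        a = convolve(single(f=0.1, R=1.0), Lineshape(0.4), fine_grid)
        b = convolve(single(E=5.0, f=0.3, R=-2.0), Lineshape(0.4), fine_grid)
        out = combine_weighted([a, b], [1.0, 0.0])
        np.testing.assert_allclose(out.epsilon, a.epsilon, rtol=1e-12)

    def test_matches_naive_accumulation(self, rng):
        grid = np.linspace(4, 8, 501)
        spectra = [self.make_spectrum(grid, s) for s in (1.0, 2.0, 5.0)]
        w = np.array([0.2, 0.3, 0.1])
        out = combine_weighted(spectra, w, renormalize=True)
        naive = np.zeros_like(grid)
        for wi, s in zip(w, spectra):
            naive += wi * s.epsilon
        naive /= w.sum()
        np.testing.assert_allclose(out.epsilon, naive, atol=1e-12)

    def test_renormalization_off_keeps_raw_sum(self):
        grid = np.linspace(4, 8, 101)
        out = combine_weighted([self.make_spectrum(grid, 1.0)], [0.25],
                               renormalize=False)
        np.testing.assert_allclose(out.epsilon, 0.25, atol=1e-15)

    def test_order_independence(self, fine_grid):
        a = convolve(single(f=0.1, R=1.0, label="a"), Lineshape(0.4), fine_grid)
        b = convolve(single(E=5.0, f=0.3, R=-2.0, label="b"), Lineshape(0.4), fine_grid)
        ab = combine_weighted([a, b], [0.6, 0.4])
        ba = combine_weighted([b, a], [0.4, 0.6])
        np.testing.assert_allclose(ab.delta_epsilon, ba.delta_epsilon, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = self.make_spectrum(np.linspace(4, 8, 101), 1.0)
        b = self.make_spectrum(np.linspace(4, 8, 102), 1.0)
        with pytest.raises(StructuralError):
            combine_weighted([a, b], [0.5, 0.5])

    def test_all_zero_weights_rejected(self):
        a = self.make_spectrum(np.linspace(4, 8, 11), 1.0)
        with pytest.raises(DataError):
            combine_weighted([a, a], [0.0, 0.0])


class TestGridAndIO:
    def test_default_grid_wavelength_window(self):
        grid = default_grid(170.0, 260.0, 2000)
        assert grid.size == 2000
        assert np.all(np.diff(grid) > 0)
        lam = EV_NM / grid
        assert lam.max() == pytest.approx(260.0)
        assert lam.min() == pytest.approx(170.0)

    def test_wavelength_axis_consistency(self, fine_grid):
        s = convolve(single(), Lineshape(0.4), fine_grid)
        np.testing.assert_allclose(s.wavelengths * s.energies, EV_NM, rtol=1e-12)

    def test_stick_csv_round_trip(self, tmp_path, rng):
        sticks = [Stick(float(e), float(f), float(r))
                  for e, f, r in zip(np.sort(rng.uniform(4, 8, 25)),
                                     rng.uniform(0, 0.3, 25),
                                     rng.normal(0, 8, 25))]
        spec = StickSpectrum(label="conf1", sticks=sticks)
        path = tmp_path / "conf1.csv"
        write_sticks(spec, path)
        back = read_sticks(path)
        assert back.label == "conf1"
        np.testing.assert_allclose(back.energies, spec.energies, rtol=1e-12)
        np.testing.assert_allclose(back.rotatories, spec.rotatories, rtol=1e-12)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("energy,osc,rot\n6.0,0.1,1.0\n")
        with pytest.raises(FormatError):
            read_sticks(path)

    def test_sticks_sorted_on_construction(self):
        s = StickSpectrum("u", [Stick(7.0, 0.1, 0), Stick(5.0, 0.2, 0)])
        assert s.energies[0] == 5.0
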