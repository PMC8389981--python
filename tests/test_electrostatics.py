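"""Charge-potential relations: Debye screening, Grahame plane, Ohshima
sphere, inversions, and the linearized map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoshs.constants import VACUUM_PERMITTIVITY
from nanoshs.electrostatics import (
    debye_parameter,
    linear_map_coefficient,
    potential_from_sigma_planar,
    potential_from_sigma_sphere,
    sigma_from_potential_planar,
    sigma_from_potential_sphere,
    zeta_to_sigma,
)
from nanoshs.errors import InvalidConditionsError, ZeroIonicStrengthError
from nanoshs.types import SolutionConditions


def grahame_mpmath(phi, cond):
    """Arbitrary-precision evaluation of the planar Grahame relation,
    independent of the numpy implementation."""
    from mpmath import mp, mpf, sinh, sqrt

    mp.dps = 50
    e = mpf("1.602176634e-19")
    kb = mpf("1.380649e-23")
    na = mpf("6.02214076e23")
    eps0 = mpf("8.8541878128e-12")
    z = mpf(cond.electrolyte_valence)
    t = mpf(repr(cond.temperature))
    er = mpf(repr(cond.relative_permittivity))
    c = mpf(repr(cond.ionic_concentration))
    kappa = sqrt(2 * na * (z * e) ** 2 * 1000 * c / (eps0 * er * kb * t))
    vt = kb * t / (z * e)
    return float(2 * eps0 * er * kappa * vt * sinh(mpf(repr(phi)) / (2 * vt)))


class TestDebye:
    def test_reference_lengths(self, water_1mM):
        """1 mM and 10 mM 1:1 electrolyte at 25 degC give the textbook
        Debye lengths of ~9.61 and ~3.04 nm."""
        lam1 = debye_parameter(water_1mM).debye_length
        lam10 = debye_parameter(
            SolutionConditions(ionic_concentration=1e-2)
        ).debye_length
        assert lam1 == pytest.approx(9.61e-9, rel=1e-3)
        assert lam10 == pytest.approx(3.04e-9, rel=1e-3)

    def test_kappa_is_inverse_length(self, water_1mM):
        k, lam = debye_parameter(water_1mM)
        assert k * lam == pytest.approx(1.0, rel=1e-15)

    def test_sqrt_concentration_scaling(self, water_1mM):
        """Quadrupling the concentration exactly halves the Debye length."""
        lam = debye_parameter(water_1mM).debye_length
        lam4 = debye_parameter(
            SolutionConditions(ionic_concentration=4e-3)
        ).debye_length
        assert lam4 == pytest.approx(lam / 2.0, rel=1e-14)

    def test_zero_concentration_distinct_error(self):
        cond = SolutionConditions(ionic_concentration=0.0)
        with pytest.raises(ZeroIonicStrengthError):
            debye_parameter(cond)
        # negative concentration is a domain error, caught at construction
        with pytest.raises(InvalidConditionsError):
            SolutionConditions(ionic_concentration=-1e-3)


class TestPlanarGrahame:
    def test_zero_potential(self, water_1mM):
        assert sigma_from_potential_planar(0.0, water_1mM) == 0.0

    @pytest.mark.parametrize("phi", [-0.042, -0.150, 0.1, 0.025])
    def test_against_arbitrary_precision(self, phi, water_1mM):
        got = sigma_from_potential_planar(phi, water_1mM)
        assert got == pytest.approx(grahame_mpmath(phi, water_1mM), rel=1e-12)

    def test_minus_42mV_value(self, water_1mM):
        """The plain-PS zeta potential maps to about -3.4 mC/m^2 on a plane."""
        assert sigma_from_potential_planar(-0.042, water_1mM) == pytest.approx(
            -3.3818e-3, rel=1e-4
        )

    def test_debye_hueckel_limit(self, water_1mM):
        """sigma/phi approaches eps0 eps_r kappa within 0.5% below 5 mV."""
        kappa = debye_parameter(water_1mM).kappa
        lin = VACUUM_PERMITTIVITY * 78.4 * kappa
        for phi in (5e-3, -5e-3, 1e-3):
            ratio = sigma_from_potential_planar(phi, water_1mM) / phi
            assert ratio == pytest.approx(lin, rel=5e-3)

    def test_closed_form_inverse(self, water_1mM):
        assert potential_from_sigma_planar(0.0, water_1mM) == 0.0
        phi = -0.150
        sigma = sigma_from_potential_planar(phi, water_1mM)
        assert potential_from_sigma_planar(sigma, water_1mM) == pytest.approx(
            phi, rel=1e-12
        )
        assert potential_from_sigma_planar(-3.3818e-3, water_1mM) == pytest.approx(
            -0.042, rel=1e-4
        )


class TestSphereOhshima:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(phi=st.floats(min_value=1e-6, max_value=0.3))
    def test_odd_symmetry(self, phi):
        cond = SolutionConditions()
        plus = sigma_from_potential_sphere(phi, 50e-9, cond)
        minus = sigma_from_potential_sphere(-phi, 50e-9, cond)
        assert minus == -plus

    def test_zero_potential(self, water_1mM):
        assert sigma_from_potential_sphere(0.0, 50e-9, water_1mM) == 0.0

    def test_nonfinite_rejected(self, water_1mM):
        with pytest.raises(ValueError):
            sigma_from_potential_sphere(float("nan"), 50e-9, water_1mM)
        with pytest.raises(ValueError):
            sigma_from_potential_sphere(-0.042, -1e-9, water_1mM)

    def test_monotone_and_exceeds_planar(self, water_1mM):
        """sigma is strictly increasing in phi and, in magnitude, at least
        the planar value (curvature stores extra charge)."""
        phi = np.linspace(-0.3, 0.3, 121)
        sp = sigma_from_potential_sphere(phi, 50e-9, water_1mM)
        pl = sigma_from_potential_planar(phi, water_1mM)
        assert np.all(np.diff(sp) > 0)
        assert np.all(np.abs(sp) >= np.abs(pl) - 1e-18)

    def test_debye_hueckel_sphere_capacitance(self, water_1mM):
        """Small-potential limit equals eps0 eps_r (1 + kappa R) phi / R."""
        r = 50e-9
        kappa = debye_parameter(water_1mM).kappa
        cap = VACUUM_PERMITTIVITY * 78.4 * (1.0 + kappa * r) / r
        for phi in (1e-3, -2e-3, 1e-6):
            got = sigma_from_potential_sphere(phi, r, water_1mM)
            assert got == pytest.approx(cap * phi, rel=5e-3)

    def test_planar_limit_large_kappaR(self, water_1mM):
        """At kappa R = 1e4 the sphere relation collapses onto Grahame
        within 0.1%."""
        kappa = debye_parameter(water_1mM).kappa
        r = 1e4 / kappa
        got = sigma_from_potential_sphere(-0.100, r, water_1mM)
        want = sigma_from_potential_planar(-0.100, water_1mM)
        assert got == pytest.approx(want, rel=1e-3)

    def test_measured_zeta_conversions(self, water_1mM):
        """-42 mV on a 100 nm sphere in 1 mM 1:1 electrolyte gives
        ~-3.9 mC/m^2; the larger-particle conversions agree loosely."""
        got = sigma_from_potential_sphere(-0.042, 50e-9, water_1mM)
        assert abs(got * 1e3 - (-3.9)) < 0.1
        # soft checks: zeta -50 / -54 mV at 200 / 500 nm
        s200 = sigma_from_potential_sphere(-0.050, 100e-9, water_1mM) * 1e3
        s500 = sigma_from_potential_sphere(-0.054, 250e-9, water_1mM) * 1e3
        assert abs(s200 - (-4.8)) / 4.8 < 0.15
        assert abs(s500 - (-5.3)) / 5.3 < 0.15


class TestSphereInverse:
    def test_zero(self, water_1mM):
        assert potential_from_sigma_sphere(0.0, 50e-9, water_1mM) == 0.0

    @pytest.mark.parametrize("phi", [-0.150, -0.042, 0.2, 0.01])
    def test_round_trip(self, phi, water_1mM):
        sigma = sigma_from_potential_sphere(phi, 50e-9, water_1mM)
        back = potential_from_sigma_sphere(sigma, 50e-9, water_1mM)
        assert abs(back - phi) < 1e-8

    def test_residual_contract(self, water_1mM):
        """The inversion leaves a relative residual below 1e-10 even for a
        very large surface charge."""
        sigma = -1.0  # C/m^2
        phi = potential_from_sigma_sphere(sigma, 50e-9, water_1mM)
        res = sigma_from_potential_sphere(phi, 50e-9, water_1mM)
        assert abs(res - sigma) / abs(sigma) < 1e-10

    def test_charge_to_potential_reference(self, water_1mM):
        """-3.9 mC/m^2 on the 100 nm particle maps back to about -42 mV."""
        phi = potential_from_sigma_sphere(-3.9e-3, 50e-9, water_1mM)
        assert -0.043 < phi < -0.041

    def test_zeta_to_sigma_state_pairing(self, water_1mM):
        state = zeta_to_sigma(-0.042, 100e-9, water_1mM)
        assert state.potential == -0.042
        assert state.charge_density < 0


class TestLinearMap:
    def test_debye_hueckel_window_slope(self, water_1mM):
        """In a +-5 mV window the least-squares slope is the exact
        Debye-Hueckel sphere capacitance to 0.5%."""
        r = 50e-9
        kappa = debye_parameter(water_1mM).kappa
        cap = VACUUM_PERMITTIVITY * 78.4 * (1.0 + kappa * r) / r
        slope = linear_map_coefficient(r, water_1mM, phi_range=5e-3)
        assert slope == pytest.approx(cap, rel=5e-3)

    def test_slope_grows_with_screening(self, water_1mM):
        s1 = linear_map_coefficient(50e-9, water_1mM)
        s10 = linear_map_coefficient(
            50e-9, SolutionConditions(ionic_concentration=1e-2)
        )
        assert s10 > s1 > 0

    def test_invalid_range(self, water_1mM):
        with pytest.raises(ValueError):
            linear_map_coefficient(50e-9, water_1mM, phi_range=0.0)

    def test_44_electrolyte_planar_agreement(self):
        """For a 4:4 electrolyte (modelling a -8 protein) at 1 uM the
        sphere and planar curves coincide within 5% of the curve scale over
        +-150 mV (the curvature correction only matters where sigma is
        negligible)."""
        cond = SolutionConditions(electrolyte_valence=4, ionic_concentration=1e-6)
        phi = np.linspace(-0.15, 0.15, 301)
        sp = sigma_from_potential_sphere(phi, 50e-9, cond)
        pl = sigma_from_potential_planar(phi, cond)
        assert np.max(np.abs(sp - pl)) / np.max(np.abs(pl)) < 0.05
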