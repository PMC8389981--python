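"""Depletion-corrected Langmuir coverage, capacity conversions, charge
update upon adsorption, and binding thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoshs.adsorption import (
    adsorbed_with_depletion,
    area_per_protein,
    capacity_per_particle,
    capacity_per_volume,
    charge_efficiency_from_endpoints,
    coverage_with_depletion,
    gibbs_from_k,
    gibbs_uncertainty,
    surface_charge_after_adsorption,
)
from nanoshs.electrostatics import potential_from_sigma_sphere, zeta_to_sigma
from nanoshs.types import ProteinSpec, SolutionConditions


def adsorbed_by_bisection(c_total, k_app, n_max_vol, iters=200):
    """Independent fixed-point oracle: bisect the mass balance
    a = n K (c-a) / (1 + K (c-a)) on [0, min(c, n)]."""
    if c_total == 0.0:
        return 0.0
    lo, hi = 0.0, min(c_total, n_max_vol)

    def f(a):
        free = c_total - a
        return n_max_vol * k_app * free / (1.0 + k_app * free) - a

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestCapacity:
    def test_reference_value(self):
        """244 proteins/particle at 4.55e14 particles/L is ~0.18 uM of
        binding sites."""
        assert capacity_per_volume(244, 4.55e14) == pytest.approx(1.844e-7, rel=1e-3)

    def test_avogadro_identity(self):
        assert capacity_per_volume(1.0, 6.02214076e23) == pytest.approx(1.0, rel=1e-14)

    def test_round_trip(self):
        n_vol = capacity_per_volume(137, 4.55e14)
        assert capacity_per_particle(n_vol, 4.55e14) == pytest.approx(137, rel=1e-14)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            capacity_per_volume(0, 1e14)


class TestCoverage:
    def test_zero_total(self):
        res = coverage_with_depletion(0.0, 3.3e9, 1.844e-7)
        assert res.theta == 0.0
        assert res.free_concentration == 0.0

    def test_reference_point(self):
        """Strong-binding HSA/100 nm conditions: 0.1 uM total protein fills
        about 54% of the available sites."""
        res = coverage_with_depletion(1e-7, 3.3e9, 1.844e-7)
        assert res.theta == pytest.approx(0.540, abs=1e-3)
        assert res.theta == pytest.approx(
            adsorbed_by_bisection(1e-7, 3.3e9, 1.844e-7) / 1.844e-7, rel=1e-10
        )

    def test_mass_balance_exact(self):
        res = coverage_with_depletion(3.7e-8, 1e9, 2e-7)
        assert res.adsorbed_concentration + res.free_concentration == pytest.approx(
            3.7e-8, rel=1e-12
        )

    def test_matches_bisection_on_grid(self):
        """Closed-form quadratic equals the fixed-point oracle to 1e-10
        across several decades, including the near-degenerate discriminant
        case c_total ~ n_max_vol with K c >> 1."""
        for c in np.geomspace(1e-10, 1e-5, 6):
            for k in np.geomspace(1e7, 1e11, 5):
                for n in np.geomspace(1e-9, 1e-6, 4):
                    got = adsorbed_with_depletion(c, k, n)
                    want = adsorbed_by_bisection(c, k, n)
                    assert got == pytest.approx(want, rel=1e-10, abs=1e-25)
        # degenerate corner
        got = adsorbed_with_depletion(1e-7, 1e12, 1e-7)
        want = adsorbed_by_bisection(1e-7, 1e12, 1e-7)
        assert got == pytest.approx(want, rel=1e-10)

    def test_no_depletion_limit(self):
        """A vanishing site concentration recovers the plain Langmuir
        isotherm to 1e-6."""
        c, k = 1e-7, 3.3e9
        theta = coverage_with_depletion(c, k, 1e-15).theta
        simple = k * c / (1.0 + k * c)
        assert theta == pytest.approx(simple, rel=1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        c=st.floats(min_value=1e-10, max_value=1e-4),
        k=st.floats(min_value=1e6, max_value=1e12),
        n=st.floats(min_value=1e-10, max_value=1e-4),
    )
    def test_theta_bounds_and_balance(self, c, k, n):
        res = coverage_with_depletion(c, k, n)
        assert 0.0 <= res.theta <= 1.0
        assert res.free_concentration >= 0.0
        assert res.adsorbed_concentration + res.free_concentration == pytest.approx(
            c, rel=1e-12
        )

    def test_monotone_in_total_and_k(self):
        cs = np.geomspace(1e-9, 1e-5, 40)
        theta_c = adsorbed_with_depletion(cs, 1e9, 2e-7) / 2e-7
        assert np.all(np.diff(theta_c) > 0)
        ks = np.geomspace(1e7, 1e12, 40)
        theta_k = np.array(
            [coverage_with_depletion(1e-7, k, 2e-7).theta for k in ks]
        )
        assert np.all(np.diff(theta_k) > 0)
        # saturation
        assert coverage_with_depletion(1e-2, 1e9, 2e-7).theta > 0.999

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            coverage_with_depletion(-1e-9, 1e9, 2e-7)


class TestGibbs:
    # (K_app / 1e8 M^-1, printed -dG kJ/mol) pairs from the fits
    PAIRS = [
        (19, 53.0),
        (33, 54.4),
        (4.8, 49.6),
        (90, 56.8),
        (270, 59.6),
        (79, 56.6),
    ]

    @pytest.mark.parametrize("k8,dg", PAIRS)
    def test_printed_pairs(self, k8, dg):
        got = gibbs_from_k(k8 * 1e8, 298.15) / 1e3
        assert got == pytest.approx(-dg, abs=0.15)

    def test_unit_k_is_zero(self):
        assert gibbs_from_k(1.0) == 0.0

    def test_strictly_decreasing(self):
        ks = np.geomspace(1e2, 1e12, 50)
        gs = np.array([gibbs_from_k(k) for k in ks])
        assert np.all(np.diff(gs) < 0)

    def test_solvent_standard_state_option(self):
        """The 55.5 M convention shifts dG by -RT ln 55.5 ~ -9.96 kJ/mol."""
        shift = gibbs_from_k(1e9, 298.15, standard_state_M=55.5) - gibbs_from_k(1e9)
        assert shift / 1e3 == pytest.approx(-9.96, abs=0.02)

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            gibbs_from_k(0.0)

    @pytest.mark.parametrize(
        "k8,dk8,want",
        [(270, 170, 1.6), (19, 5, 0.7), (33, 17, 1.3), (90, 50, 1.4)],
    )
    def test_uncertainty_pairs(self, k8, dk8, want):
        got = gibbs_uncertainty(k8 * 1e8, dk8 * 1e8, 298.15) / 1e3
        assert got == pytest.approx(want, abs=0.1)

    def test_uncertainty_linear_and_zero(self):
        assert gibbs_uncertainty(1e9, 0.0) == 0.0
        one = gibbs_uncertainty(1e9, 1e8)
        assert gibbs_uncertainty(1e9, 3e8) == pytest.approx(3 * one, rel=1e-12)


class TestFootprint:
    @pytest.mark.parametrize(
        "d_nm,n_max,want",
        [(100, 244, 129), (200, 1179, 106), (500, 18614, 42)],
    )
    def test_mean_area_series(self, d_nm, n_max, want):
        got = area_per_protein(n_max, d_nm * 1e-9)
        assert got == pytest.approx(want, abs=1.0)

    def test_single_site(self):
        assert area_per_protein(1, 100e-9) == pytest.approx(
            math.pi * 100**2, rel=1e-12
        )


class TestChargeUpdate:
    HSA = ProteinSpec("HSA", -8.0)

    def test_zero_coverage_unchanged(self):
        sigma = surface_charge_after_adsorption(0.0, -3.9e-3, self.HSA, 244, 100e-9)
        assert sigma == -3.9e-3

    def test_linear_midpoint(self):
        s0 = surface_charge_after_adsorption(0.0, -3.9e-3, self.HSA, 244, 100e-9, 0.2)
        s1 = surface_charge_after_adsorption(1.0, -3.9e-3, self.HSA, 244, 100e-9, 0.2)
        mid = surface_charge_after_adsorption(0.5, -3.9e-3, self.HSA, 244, 100e-9, 0.2)
        assert mid == pytest.approx(0.5 * (s0 + s1), rel=1e-12)

    def test_magnitude_reduction(self):
        """Adsorption screens the bare charge: |sigma| decreases."""
        s1 = surface_charge_after_adsorption(1.0, -3.9e-3, self.HSA, 244, 100e-9, 0.1)
        assert abs(s1) < 3.9e-3

    def test_endpoint_calibration_round_trip(self):
        """Calibrated to the measured zeta endpoints (-42 mV bare, -31 mV
        saturated with HSA), the charge update reproduces the saturated
        potential through the sphere inversion."""
        cond = SolutionConditions()
        bare = zeta_to_sigma(-42e-3, 100e-9, cond).charge_density
        sat = zeta_to_sigma(-31e-3, 100e-9, cond).charge_density
        eta = charge_efficiency_from_endpoints(bare, sat, self.HSA, 244, 100e-9)
        assert 0.0 < eta < 1.0
        s_full = surface_charge_after_adsorption(1.0, bare, self.HSA, 244, 100e-9, eta)
        phi_full = potential_from_sigma_sphere(s_full, 50e-9, cond)
        assert phi_full == pytest.approx(-31e-3, rel=1e-6)

    def test_unreachable_endpoints_rejected(self):
        with pytest.raises(ValueError):
            # saturated charge larger in magnitude than bare: wrong direction
            charge_efficiency_from_endpoints(-3.9e-3, -8e-3, self.HSA, 244, 100e-9)

    def test_theta_out_of_range(self):
        with pytest.raises(ValueError):
            surface_charge_after_adsorption(1.5, -3.9e-3, self.HSA, 244, 100e-9)
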