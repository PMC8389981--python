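"""Depletion-corrected Langmuir adsorption and binding thermodynamics.

The monolayer capacity is large enough, at the nanoparticle number densities
used in SHS titrations, that adsorption measurably depletes the bulk; the
coverage therefore solves the coupled system

    adsorbed = n_max_vol * K c_free / (1 + K c_free)
    c_free   = c_total - adsorbed

whose physical root is a closed-form quadratic. The apparent Gibbs free
energy follows from the apparent binding constant via
Delta G = -R T ln(K_app c0) with standard state c0 = 1 M by default.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from .constants import AVOGADRO, ELEMENTARY_CHARGE, GAS_CONSTANT
from .types import CoverageResult, ProteinSpec

__all__ = [
    "capacity_per_volume",
    "capacity_per_particle",
    "coverage_with_depletion",
    "adsorbed_with_depletion",
    "surface_charge_after_adsorption",
    "charge_efficiency_from_endpoints",
    "gibbs_from_k",
    "gibbs_uncertainty",
    "area_per_protein",
]

ArrayLike = Union[float, np.ndarray]


def capacity_per_volume(n_max_per_particle: float, number_density: float) -> float:
    """Monolayer capacity as a molar concentration.

    N_max_vol (mol/L) = count per particle x particles per litre / N_A.
    """
    if n_max_per_particle <= 0 or number_density <= 0:
        raise ValueError("capacity inputs must be positive")
    return n_max_per_particle * number_density / AVOGADRO


def capacity_per_particle(n_max_vol: float, number_density: float) -> float:
    """Exact inverse of :func:`capacity_per_volume`."""
    if n_max_vol <= 0 or number_density <= 0:
        raise ValueError("capacity inputs must be positive")
    return n_max_vol * AVOGADRO / number_density


def adsorbed_with_depletion(
    c_total: ArrayLike, k_app: float, n_max_vol: float
) -> ArrayLike:
    """Adsorbed molar concentration from the depletion-corrected isotherm.

    Uses the cancellation-free root of the quadratic,
    adsorbed = 2 c n / (S + sqrt(S^2 - 4 c n)), S = c + n + 1/K,
    which is the physical (smaller) root and stays accurate when the
    discriminant nearly vanishes (c_total ~ n_max_vol with K c >> 1).
    """
    c_total = np.asarray(c_total, dtype=float)
    if np.any(c_total < 0):
        raise ValueError("total concentration must be >= 0")
    if not (k_app > 0 and n_max_vol > 0):
        raise ValueError("k_app and n_max_vol must be positive")
    s = c_total + n_max_vol + 1.0 / k_app
    with np.errstate(over="ignore"):  # huge 1/K during optimizer excursions
        disc = s * s - 4.0 * c_total * n_max_vol
        adsorbed = 2.0 * c_total * n_max_vol / (s + np.sqrt(np.maximum(disc, 0.0)))
    return adsorbed if adsorbed.ndim else float(adsorbed)


def coverage_with_depletion(
    c_total: float, k_app: float, n_max_vol: float
) -> CoverageResult:
    """Fractional coverage theta with its mass balance at one total
    concentration. ``theta = adsorbed / n_max_vol``; free = total - adsorbed."""
    adsorbed = adsorbed_with_depletion(float(c_total), k_app, n_max_vol)
    free = float(c_total) - adsorbed
    return CoverageResult(
        theta=min(adsorbed / n_max_vol, 1.0),
        adsorbed_concentration=adsorbed,
        free_concentration=max(free, 0.0),
    )


def surface_charge_after_adsorption(
    theta: ArrayLike,
    bare_sigma: float,
    protein: ProteinSpec,
    n_max_per_particle: float,
    diameter: float,
    efficiency: float = 1.0,
) -> ArrayLike:
    """Surface charge density after partial monolayer adsorption.

    Adsorbed protein arrives dressed in its counterion cloud; experimentally
    the magnitude of the surface potential drops even when protein and
    surface are like-charged. The model therefore treats the adsorbed layer
    as *screening* the bare charge,

        sigma(theta) = sigma_bare
                       - sign(sigma_bare) * eta * theta * N_max |z_p| e / (pi D^2),

    linear in theta, where eta in [0, 1] is the fraction of the protein's
    formal charge that is effective as screening (the microscopic
    bookkeeping is not resolved by the measurement). eta can be calibrated
    from bare/saturated zeta endpoints with
    :func:`charge_efficiency_from_endpoints`.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("theta must lie in [0, 1]")
    if not (0 <= efficiency <= 1):
        raise ValueError("efficiency must lie in [0, 1]")
    per_area = (
        n_max_per_particle * abs(protein.net_valence) * ELEMENTARY_CHARGE
        / (math.pi * diameter**2)
    )
    sign = math.copysign(1.0, bare_sigma) if bare_sigma != 0 else 0.0
    out = bare_sigma - sign * efficiency * theta * per_area
    return out if out.ndim else float(out)


def charge_efficiency_from_endpoints(
    bare_sigma: float,
    saturated_sigma: float,
    protein: ProteinSpec,
    n_max_per_particle: float,
    diameter: float,
) -> float:
    """Screening efficiency eta that maps sigma(0)=bare to sigma(1)=saturated.

    Both endpoints typically come from zeta-potential measurements converted
    through the sphere charge-potential relation.
    """
    per_area = (
        n_max_per_particle * abs(protein.net_valence) * ELEMENTARY_CHARGE
        / (math.pi * diameter**2)
    )
    sign = math.copysign(1.0, bare_sigma)
    eta = (bare_sigma - saturated_sigma) * sign / per_area
    if not (0 <= eta <= 1):
        raise ValueError(
            f"endpoints imply efficiency {eta:.3g} outside [0, 1]; "
            "the protein term cannot reproduce them"
        )
    return float(eta)


def gibbs_from_k(
    k_app: float, temperature: float = 298.15, standard_state_M: float = 1.0
) -> float:
    """Apparent standard Gibbs free energy of adsorption (J/mol).

    Delta G_app = -R T ln(K_app * c0). The default standard state c0 = 1 M;
    negative whenever K_app c0 > 1.
    """
    if not (k_app > 0):
        raise ValueError("K_app must be positive")
    return -GAS_CONSTANT * temperature * math.log(k_app * standard_state_M)


def gibbs_uncertainty(
    k_app: float, dk_app: float, temperature: float = 298.15
) -> float:
    """First-order propagated uncertainty of Delta G (J/mol):
    delta(Delta G) = R T * (dK/K)."""
    if not (k_app > 0):
        raise ValueError("K_app must be positive")
    if dk_app < 0:
        raise ValueError("dK must be >= 0")
    return GAS_CONSTANT * temperature * dk_app / k_app


def area_per_protein(n_max_per_particle: float, diameter: float) -> float:
    """Mean footprint per adsorbed protein at saturation, in nm^2:
    pi D^2 / N_max (sphere surface area over monolayer count)."""
    if not (n_max_per_particle > 0 and diameter > 0):
        raise ValueError("inputs must be positive")
    return math.pi * diameter**2 / n_max_per_particle * 1e18
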