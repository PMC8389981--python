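"""Forward model for nonresonant second-harmonic scattering (SHS) from
charged spheres.

The detected second-harmonic field has two coherent parts: a surface
second-order term (chi2) and a bulk third-order term (chi3) from solvent
molecules aligned and polarized by the static double-layer field, which is
proportional to the surface potential. Within the nonlinear
Rayleigh-Gans-Debye approximation both reduce to scalar form factors:
spherical-Bessel closed forms for the surface, and a one-dimensional radial
integral over the screened Coulomb field for the bulk.

For a fixed scattering angle and ionic strength the form factors are
constants, and a titration changes the intensity only through the surface
coverage; :func:`titration_intensity` provides that reduced link model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Union

import numpy as np
from scipy.integrate import quad
from scipy.special import spherical_jn

from .electrostatics import debye_parameter, particle_surface_state
from .types import (
    NanoparticleSpec,
    OpticalAmplitudes,
    ScatteringGeometry,
    SolutionConditions,
)

__all__ = [
    "scattering_q",
    "surface_form_factor",
    "bulk_chi3_form_factor",
    "pattern",
    "PatternResult",
    "titration_intensity",
]

ArrayLike = Union[float, np.ndarray]

#: Scalar polarization channel weights: the reduction of the full tensor
#: algebra to one angular envelope per polarization combination. Both vanish
#: in the exact forward direction (no collinear second-harmonic radiation).
_CHANNEL_WEIGHTS = {
    "ppp": lambda theta: np.sin(theta),
    "pss": lambda theta: np.sin(theta) * np.cos(theta / 2.0),
}


def scattering_q(geometry: ScatteringGeometry) -> float:
    """Scattering wave vector magnitude (1/m).

    q = (8 pi n / lambda_fund) sin(theta/2), from |k_2w| = 2|k_w| for a
    dispersionless medium.
    """
    theta = math.radians(geometry.scattering_angle)
    return (
        8.0
        * math.pi
        * geometry.medium_refractive_index
        / geometry.fundamental_wavelength
        * math.sin(theta / 2.0)
    )


def surface_form_factor(q_r: ArrayLike, radius: float = 1.0, order: int = 0) -> ArrayLike:
    """Surface form factor: integral over the sphere of exp(i q.r) times the
    ``order``-th power of the outward normal projected on q-hat.

    Closed forms in spherical Bessel functions (x = qR):

    ========  =============================
    order 0   4 pi R^2 j0(x)
    order 1   4 pi R^2 i j1(x)
    order 2   4 pi R^2 (j0(x) - 2 j2(x))/3
    order 3   4 pi R^2 i (3 j1(x) - 2 j3(x))/5
    ========  =============================

    At q = 0 the order-0 factor is the total surface area 4 pi R^2 and the
    odd orders vanish by symmetry.
    """
    x = np.asarray(q_r, dtype=float)
    if np.any(x < 0):
        raise ValueError("qR must be >= 0")
    area = 4.0 * math.pi * radius**2
    if order == 0:
        out = area * spherical_jn(0, x) + 0j
    elif order == 1:
        out = area * 1j * spherical_jn(1, x)
    elif order == 2:
        out = area * (spherical_jn(0, x) - 2.0 * spherical_jn(2, x)) / 3.0 + 0j
    elif order == 3:
        out = area * 1j * (3.0 * spherical_jn(1, x) - 2.0 * spherical_jn(3, x)) / 5.0
    else:
        raise ValueError("order must be 0..3")
    return out if np.ndim(out) else complex(out)


def bulk_chi3_form_factor(
    kappa_r: float,
    q_r: float,
    phi0: float = 1.0,
    radius: float = 1.0,
    tail_lengths: float = 20.0,
) -> complex:
    """Bulk chi3 form factor: volume integral of exp(i q.r) weighted by the
    static double-layer field outside the sphere.

    With the linearized (Debye-Hueckel) profile
    Phi(r) = Phi0 (R/r) exp(-kappa (r-R)), the radial field is
    E_r = Phi0 R (1/r^2 + kappa/r) exp(-kappa (r-R)) and the projection of
    the vector integral on q-hat reduces to

        F3 = 4 pi i Phi0 R^2 * Int_1^inf (1 + kR x) exp(-kR (x-1)) j1(qR x) dx

    (x = r/R). The integral is evaluated by adaptive quadrature truncated at
    x = 1 + tail_lengths/kR; the neglected tail is bounded by
    exp(-tail_lengths) relative to the retained part. Strictly linear in
    Phi0 and zero at zero potential.
    """
    if not (kappa_r > 0):
        raise ValueError("kappa R must be positive")
    if q_r < 0:
        raise ValueError("qR must be >= 0")
    if phi0 == 0.0 or q_r == 0.0:
        return 0.0 + 0.0j
    upper = 1.0 + tail_lengths / kappa_r

    def integrand(x: float) -> float:
        return (1.0 + kappa_r * x) * math.exp(-kappa_r * (x - 1.0)) * spherical_jn(1, q_r * x)

    # subdivide at the j1 oscillation scale for reliable adaptive quadrature
    n_osc = max(int(q_r * (upper - 1.0) / math.pi), 1)
    val, err = quad(integrand, 1.0, upper, limit=max(200, 4 * n_osc), epsabs=1e-12, epsrel=1e-10)
    if abs(err) > 1e-6 * abs(val) + 1e-9:
        raise RuntimeError(f"chi3 quadrature did not converge (err={err:.2e})")
    return 4.0 * math.pi * 1j * phi0 * radius**2 * val


@dataclass
class PatternResult:
    """Angle-resolved SHS pattern for one particle/solution configuration."""

    angles: np.ndarray  # degrees
    intensities: Dict[str, np.ndarray]  # polarization -> arb intensity
    peak_angles: Dict[str, float]
    surface_potential: float  # V, used in the chi3 term
    metadata: dict = field(default_factory=dict)

    def peak_angle(self, polarization: str = "ppp") -> float:
        return self.peak_angles[polarization]


def _channel_amplitude(
    theta_rad: np.ndarray,
    q: np.ndarray,
    radius: float,
    kappa: float,
    phi0: float,
    amplitudes: OpticalAmplitudes,
    polarization: str,
) -> np.ndarray:
    weight = _CHANNEL_WEIGHTS[polarization](theta_rad)
    f_surf = np.array([surface_form_factor(qi * radius, radius, order=1) for qi in q])
    f_bulk = np.array(
        [bulk_chi3_form_factor(kappa * radius, qi * radius, 1.0, radius) for qi in q]
    )
    phase = np.exp(1j * amplitudes.relative_phase)
    return weight * (
        amplitudes.chi2_amplitude * f_surf
        + phase * amplitudes.chi3_amplitude * phi0 * f_bulk
    )


def pattern(
    amplitudes: OpticalAmplitudes,
    particle: NanoparticleSpec,
    cond: SolutionConditions,
    angles: Sequence[float] = None,
    geometry: ScatteringGeometry = None,
    polarizations: Sequence[str] = ("ppp", "pss"),
) -> PatternResult:
    """Angle-resolved SHS intensity pattern for one particle species.

    I(theta) per polarization is |w(theta) (chi2 F_surf(qR)
    + e^{i phase} chi3 Phi0 F3(kR, qR))|^2 scaled by the particle number
    density (incoherent single-particle sum). The surface potential Phi0 is
    resolved from the particle's bare surface charge (numerical sphere
    inversion at these conditions) or, failing that, its zeta potential.
    """
    if geometry is None:
        geometry = ScatteringGeometry()
    if angles is None:
        angles = np.arange(5.0, 176.0, 1.0)
    angles = np.asarray(angles, dtype=float)
    theta_rad = np.radians(angles)
    q = (
        8.0
        * math.pi
        * geometry.medium_refractive_index
        / geometry.fundamental_wavelength
        * np.sin(theta_rad / 2.0)
    )
    kappa = debye_parameter(cond).kappa
    state = particle_surface_state(particle, cond)
    intensities, peaks = {}, {}
    for pol in polarizations:
        amp = _channel_amplitude(
            theta_rad, q, particle.radius, kappa, state.potential, amplitudes, pol
        )
        inten = particle.number_density * np.abs(amp) ** 2
        intensities[pol] = inten
        peaks[pol] = float(angles[int(np.argmax(inten))])
    return PatternResult(
        angles=angles,
        intensities=intensities,
        peak_angles=peaks,
        surface_potential=state.potential,
        metadata={
            "kappa_per_m": kappa,
            "surface_charge_C_m2": state.charge_density,
            "zeta_equals_surface_potential": particle.surface_charge is None,
        },
    )


def titration_intensity(
    theta_cov: ArrayLike,
    i_0: float,
    i_sat: float,
    link: str = "field_linear",
) -> ArrayLike:
    """Fixed-angle SHS intensity as a function of fractional coverage.

    For a fixed angle and ionic strength the form factors are constants and
    the scattered *field* tracks the surface charge, which the adsorption
    model makes linear in coverage. Hence the default link

        sqrt(I) = a - b theta,  a = sqrt(I_0), b = sqrt(I_0) - sqrt(I_sat)

    i.e. I(theta) = (a - b theta)^2, convex in theta. The alternative
    ``intensity_linear`` link, I = I_0 - (I_0 - I_sat) theta, is affine and
    kept for sensitivity analysis. I_sat > I_0 (charge-increasing adsorbate)
    is allowed in both links.
    """
    theta = np.asarray(theta_cov, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("coverage must lie in [0, 1]")
    if i_0 < 0 or i_sat < 0:
        raise ValueError("intensities must be >= 0")
    if link == "field_linear":
        a = math.sqrt(i_0)
        b = a - math.sqrt(i_sat)
        out = (a - b * theta) ** 2
    elif link == "intensity_linear":
        out = i_0 - (i_0 - i_sat) * theta
    else:
        raise ValueError("link must be 'field_linear' or 'intensity_linear'")
    return out if out.ndim else float(out)
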