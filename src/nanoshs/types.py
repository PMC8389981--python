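"""Domain containers shared across the package.

Conventions: lengths in metres, potentials in volts, surface charge densities
in C/m^2, concentrations in mol/L, number densities in 1/L, temperatures in
kelvin. Plain frozen dataclasses with invariant checks in ``__post_init__``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import STANDARD_TEMPERATURE, WATER_MOLARITY, WATER_RELATIVE_PERMITTIVITY
from .errors import InvalidConditionsError


@dataclass(frozen=True)
class SolutionConditions:
    """Bulk electrolyte solution: temperature, permittivity and a symmetric
    z:z electrolyte at the given molar concentration."""

    temperature: float = STANDARD_TEMPERATURE
    relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY
    electrolyte_valence: int = 1
    ionic_concentration: float = 1e-3  # mol/L

    def __post_init__(self):
        if not (self.temperature > 0):
            raise InvalidConditionsError("temperature must be positive (K)")
        if not (self.relative_permittivity > 0):
            raise InvalidConditionsError("relative permittivity must be positive")
        if int(self.electrolyte_valence) != self.electrolyte_valence or self.electrolyte_valence < 1:
            raise InvalidConditionsError("electrolyte valence must be a positive integer")
        if self.ionic_concentration < 0 or not math.isfinite(self.ionic_concentration):
            raise InvalidConditionsError("ionic concentration must be finite and >= 0")


@dataclass(frozen=True)
class SurfaceState:
    """Paired surface potential (V) and surface charge density (C/m^2).

    The charge-potential relation is odd and monotone, so the two fields
    always carry the same sign (or are both zero).
    """

    potential: float
    charge_density: float

    def __post_init__(self):
        if self.potential * self.charge_density < 0:
            raise InvalidConditionsError(
                "potential and charge density must share a sign (odd monotone relation)"
            )


@dataclass(frozen=True)
class NanoparticleSpec:
    """Spherical nanoparticle: geometry, suspension number density and either
    a measured zeta potential or a bare surface charge density."""

    diameter: float  # m
    number_density: float  # particles per litre
    zeta_potential: Optional[float] = None  # V
    surface_charge: Optional[float] = None  # C/m^2
    label: str = ""

    def __post_init__(self):
        if not (self.diameter > 0):
            raise InvalidConditionsError("diameter must be positive (m)")
        if not (self.number_density > 0):
            raise InvalidConditionsError("number density must be positive (1/L)")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def surface_area(self) -> float:
        """Sphere surface area pi*D^2 (m^2)."""
        return math.pi * self.diameter**2


@dataclass(frozen=True)
class ProteinSpec:
    """Adsorbing protein: name and signed net valence (elementary charges)
    at the working pH."""

    name: str
    net_valence: float

    def __post_init__(self):
        if not self.name:
            raise InvalidConditionsError("protein name must be nonempty")
        if not math.isfinite(self.net_valence):
            raise InvalidConditionsError("protein net valence must be finite")


@dataclass(frozen=True)
class AdsorptionParams:
    """Langmuir parameters: apparent binding constant K_app (1/M) and
    monolayer capacity per particle. Only the ratio K = k_a/k_d is
    identifiable; rates are never separated."""

    binding_constant_app: float  # 1/M
    n_max_per_particle: float  # count
    solvent_molarity: float = WATER_MOLARITY  # mol/L

    def __post_init__(self):
        if not (self.binding_constant_app > 0):
            raise InvalidConditionsError("K_app must be positive (1/M)")
        if not (self.n_max_per_particle > 0):
            raise InvalidConditionsError("N_max per particle must be positive")


@dataclass(frozen=True)
class CoverageResult:
    """Fractional coverage with its mass balance: adsorbed + free = total."""

    theta: float
    adsorbed_concentration: float  # mol/L
    free_concentration: float  # mol/L

    def __post_init__(self):
        if not (-1e-12 <= self.theta <= 1 + 1e-12):
            raise InvalidConditionsError("coverage must lie in [0, 1]")
        if self.free_concentration < -1e-30:
            raise InvalidConditionsError("free concentration must be >= 0")

    @property
    def total_concentration(self) -> float:
        return self.adsorbed_concentration + self.free_concentration


@dataclass(frozen=True)
class OpticalAmplitudes:
    """Effective scalar susceptibility amplitudes of the SHS forward model.

    ``chi2_amplitude`` is the surface second-order amplitude (arb. units),
    ``chi3_amplitude`` the bulk third-order amplitude per volt of surface
    potential, and ``relative_phase`` the phase (rad) between the two.
    """

    chi2_amplitude: float = 1.0
    chi3_amplitude: float = 25.0  # per volt
    relative_phase: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.chi2_amplitude) and math.isfinite(self.chi3_amplitude)):
            raise InvalidConditionsError("amplitudes must be finite")
        if not (0 <= self.relative_phase < 2 * math.pi):
            raise InvalidConditionsError("relative phase must lie in [0, 2*pi)")


@dataclass(frozen=True)
class ScatteringGeometry:
    """Fixed-angle scattering geometry for the second-harmonic process."""

    fundamental_wavelength: float = 1028e-9  # m
    medium_refractive_index: float = 1.33
    scattering_angle: float = 40.0  # degrees, in-plane
    polarization: str = "ppp"

    def __post_init__(self):
        if not (self.fundamental_wavelength > 0):
            raise InvalidConditionsError("wavelength must be positive")
        if not (0 < self.scattering_angle < 180):
            raise InvalidConditionsError("scattering angle must lie in (0, 180) degrees")
        if self.polarization not in ("ppp", "pss"):
            raise InvalidConditionsError("polarization must be 'ppp' or 'pss'")


@dataclass(frozen=True)
class TitrationCurve:
    """One fixed-angle titration: SHS intensity versus total protein
    concentration, tagged by scattering angle and polarization.

    Concentrations must be strictly increasing; intensities nonnegative;
    errors, where given, strictly positive.
    """

    concentrations: np.ndarray  # mol/L, strictly increasing
    intensities: np.ndarray  # arb
    intensity_errors: Optional[np.ndarray] = None
    scattering_angle: float = 40.0
    polarization: str = "ppp"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "intensities", i)
        if c.ndim != 1 or i.shape != c.shape:
            raise InvalidConditionsError("concentrations and intensities must be equal-length 1-D")
        if c.size and c[0] < 0:
            raise InvalidConditionsError("concentrations must be >= 0")
        if np.any(np.diff(c) <= 0):
            raise InvalidConditionsError("concentrations must be strictly increasing")
        if np.any(i < 0):
            raise InvalidConditionsError("intensities must be >= 0")
        if self.intensity_errors is not None:
            e = np.asarray(self.intensity_errors, dtype=float)
            object.__setattr__(self, "intensity_errors", e)
            if e.shape != c.shape:
                raise InvalidConditionsError("errors must match the data shape")
            if np.any(e <= 0):
                raise InvalidConditionsError("intensity errors must be > 0")

    def __len__(self) -> int:
        return self.concentrations.size

    @property
    def key(self) -> tuple:
        return (self.scattering_angle, self.polarization)
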