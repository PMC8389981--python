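"""Synthetic SHS titration curves and angle patterns.

Emulates the statistical structure of fixed-angle titration measurements in
the strong-binding / strong-depletion regime (half-saturation free
concentration far below the volumetric monolayer capacity) and of
angle-resolved screening experiments. Each titration point is the mean of a
number of replicate draws with multiplicative Gaussian noise, and the
recorded error is the standard error of that mean - matching the practice of
averaging each point over at least ten one-second acquisitions. Every
generated dataset is paired with its ground-truth record so recovery can be
scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .adsorption import adsorbed_with_depletion, capacity_per_volume
from .errors import InvalidConditionsError
from .optics import PatternResult, pattern, titration_intensity
from .types import (
    AdsorptionParams,
    NanoparticleSpec,
    OpticalAmplitudes,
    ProteinSpec,
    SolutionConditions,
    TitrationCurve,
)

__all__ = ["SimulationScenario", "make_titration", "make_pattern", "scenario_presets"]

#: Default intensity endpoints: the saturated field amplitude follows the
#: measured zeta drop from -42 to -31 mV on plain PS + HSA, so
#: I_sat/I_0 = (31/42)^2 under the field-linear link.
_DEFAULT_I0 = 1.0
_DEFAULT_ISAT = (31.0 / 42.0) ** 2


def _default_grid() -> np.ndarray:
    """15 log-spaced points, 1 nM - 10 uM, straddling the depletion
    breakpoint of every preset."""
    return np.geomspace(1e-9, 1e-5, 15)


@dataclass(frozen=True)
class SimulationScenario:
    """Complete recipe for one synthetic experiment (ground truth included)."""

    particle: NanoparticleSpec
    protein: ProteinSpec
    adsorption: AdsorptionParams
    solution: SolutionConditions = SolutionConditions()
    amplitudes: Tuple[float, float] = (_DEFAULT_I0, _DEFAULT_ISAT)  # (I_0, I_sat)
    optical: OpticalAmplitudes = OpticalAmplitudes()
    concentration_grid: np.ndarray = field(default_factory=_default_grid)
    noise_model: str = "multiplicative_gaussian"
    noise_level: float = 0.02
    replicates: int = 10
    scattering_angles: Tuple[float, ...] = (40.0, 90.0)
    polarization: str = "ppp"
    link: str = "field_linear"
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        grid = np.asarray(self.concentration_grid, dtype=float)
        object.__setattr__(self, "concentration_grid", grid)
        if np.any(np.diff(grid) <= 0):
            raise InvalidConditionsError("concentration grid must be strictly increasing")
        if self.noise_level < 0:
            raise InvalidConditionsError("noise level must be >= 0")
        if self.noise_model not in ("multiplicative_gaussian", "additive_gaussian"):
            raise InvalidConditionsError("unknown noise model")
        if self.replicates < 1:
            raise InvalidConditionsError("replicates must be >= 1")
        if self.seed is None:
            raise InvalidConditionsError("a seed is required")

    @property
    def n_max_vol(self) -> float:
        return capacity_per_volume(
            self.adsorption.n_max_per_particle, self.particle.number_density
        )

    def truth(self) -> dict:
        """Ground-truth record paired with every generated dataset."""
        return {
            "name": self.name,
            "k_app_per_M": self.adsorption.binding_constant_app,
            "n_max_per_particle": self.adsorption.n_max_per_particle,
            "n_max_vol_M": self.n_max_vol,
            "number_density_per_L": self.particle.number_density,
            "diameter_m": self.particle.diameter,
            "protein": self.protein.name,
            "i_0": self.amplitudes[0],
            "i_sat": self.amplitudes[1],
            "noise_model": self.noise_model,
            "noise_level": self.noise_level,
            "replicates": self.replicates,
            "link": self.link,
            "seed": self.seed,
        }


def _noisy_point(
    value: float, scenario: SimulationScenario, rng: np.random.Generator
) -> Tuple[float, float]:
    """Mean and standard error over the scenario's replicate draws."""
    if scenario.noise_level == 0.0:
        return value, max(abs(value) * 1e-6, 1e-12)  # nominal error for weighting
    if scenario.noise_model == "multiplicative_gaussian":
        draws = value * (1.0 + scenario.noise_level * rng.standard_normal(scenario.replicates))
    else:
        draws = value + scenario.noise_level * rng.standard_normal(scenario.replicates)
    draws = np.clip(draws, 0.0, None)
    mean = float(np.mean(draws))
    if scenario.replicates > 1:
        sem = float(np.std(draws, ddof=1) / math.sqrt(scenario.replicates))
    else:
        sem = scenario.noise_level * max(abs(value), 1e-30)
    return mean, max(sem, 1e-12)


def make_titration(
    scenario: SimulationScenario, seed: Optional[int] = None
) -> Tuple[List[TitrationCurve], dict]:
    """Generate one titration curve per configured scattering angle.

    The noiseless model is coverage (depletion-corrected Langmuir) pushed
    through the intensity link; noise and replicate averaging are applied
    per point. Returns the curves and the paired ground-truth record.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n_vol = scenario.n_max_vol
    theta = (
        adsorbed_with_depletion(
            scenario.concentration_grid, scenario.adsorption.binding_constant_app, n_vol
        )
        / n_vol
    )
    i_0, i_sat = scenario.amplitudes
    clean = titration_intensity(np.clip(theta, 0, 1), i_0, i_sat, scenario.link)
    curves = []
    for angle in scenario.scattering_angles:
        vals, errs = [], []
        for v in clean:
            m, s = _noisy_point(float(v), scenario, rng)
            vals.append(m)
            errs.append(s)
        curves.append(
            TitrationCurve(
                concentrations=scenario.concentration_grid.copy(),
                intensities=np.array(vals),
                intensity_errors=np.array(errs),
                scattering_angle=angle,
                polarization=scenario.polarization,
                metadata={
                    "scenario": scenario.name,
                    "seed": scenario.seed,
                    # replicate count behind the SEM error bars (meaningful
                    # only when the points actually carry noise)
                    **(
                        {"replicates": int(scenario.replicates)}
                        if scenario.noise_level > 0 and scenario.replicates > 1
                        else {}
                    ),
                },
            )
        )
    return curves, scenario.truth()


def make_pattern(
    scenario: SimulationScenario,
    angles: Optional[Sequence[float]] = None,
    ionic_pair: Tuple[float, float] = (1e-5, 1e-2),
    seed: Optional[int] = None,
) -> Dict[str, PatternResult]:
    """Generate a low/high ionic-strength pair of angle patterns with noise.

    The particle's surface charge is held fixed across the pair (the
    potential drops with added salt through the sphere relation), mirroring
    a screening experiment.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    particle = scenario.particle
    if particle.surface_charge is None:
        from .electrostatics import zeta_to_sigma

        state = zeta_to_sigma(particle.zeta_potential, particle.diameter, scenario.solution)
        particle = replace(particle, surface_charge=state.charge_density, zeta_potential=None)
    out = {}
    for tag, conc in zip(("low_salt", "high_salt"), ionic_pair):
        cond = replace(scenario.solution, ionic_concentration=conc)
        res = pattern(scenario.optical, particle, cond, angles=angles)
        noisy = {}
        for pol, inten in res.intensities.items():
            vals = [
                _noisy_point(float(v), scenario, rng)[0] for v in inten
            ]
            noisy[pol] = np.array(vals)
        res.metadata["noisy_intensities"] = noisy
        res.metadata["ionic_concentration_M"] = conc
        out[tag] = res
    return out


def _preset(
    name: str,
    diameter_nm: float,
    density_per_L: float,
    zeta_mV: float,
    protein: ProteinSpec,
    k_app: float,
    n_max: float,
    label: str,
) -> SimulationScenario:
    return SimulationScenario(
        particle=NanoparticleSpec(
            diameter=diameter_nm * 1e-9,
            number_density=density_per_L,
            zeta_potential=zeta_mV * 1e-3,
            label=label,
        ),
        protein=protein,
        adsorption=AdsorptionParams(binding_constant_app=k_app, n_max_per_particle=n_max),
        name=name,
    )


def scenario_presets() -> Dict[str, SimulationScenario]:
    """The nine reference parameter sets: six protein/functionalization
    combinations on 100 nm particles and the three-size HSA series, each
    carrying its fitted (K_app, N_max) as ground truth.

    Number densities: 4.55e14, 1.31e13 and 1.81e12 particles/L for the 100,
    200 and 500 nm particles. Net valences: HSA -8 (measured at pH 6.6);
    Fbg -10 and Tf -2 are isoelectric-point-based defaults.
    """
    hsa = ProteinSpec("HSA", -8.0)
    fbg = ProteinSpec("Fbg", -10.0)
    tf = ProteinSpec("Tf", -2.0)
    d100, d200, d500 = 4.55e14, 1.31e13, 1.81e12
    presets = {
        "ps_fbg_100nm": _preset("ps_fbg_100nm", 100, d100, -42, fbg, 19e8, 130, "PS"),
        "ps_hsa_100nm": _preset("ps_hsa_100nm", 100, d100, -42, hsa, 33e8, 244, "PS"),
        "ps_tf_100nm": _preset("ps_tf_100nm", 100, d100, -42, tf, 4.8e8, 183, "PS"),
        "pscooh_fbg_100nm": _preset("pscooh_fbg_100nm", 100, d100, -44, fbg, 90e8, 38, "PS-COOH"),
        "pscooh_hsa_100nm": _preset("pscooh_hsa_100nm", 100, d100, -44, hsa, 270e8, 137, "PS-COOH"),
        "pscooh_tf_100nm": _preset("pscooh_tf_100nm", 100, d100, -44, tf, 79e8, 131, "PS-COOH"),
        "ps_hsa_size_100nm": _preset("ps_hsa_size_100nm", 100, d100, -42, hsa, 3.3e9, 244, "PS"),
        "ps_hsa_size_200nm": _preset("ps_hsa_size_200nm", 200, d200, -50, hsa, 80e9, 1179, "PS"),
        "ps_hsa_size_500nm": _preset("ps_hsa_size_500nm", 500, d500, -54, hsa, 3.0e9, 18614, "PS"),
    }
    return presets
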