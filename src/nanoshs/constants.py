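"""Physical constants (CODATA 2018) shared by all modules.

All values are in SI units; concentrations elsewhere in the package are
mol/L ("M") and are converted to mol/m^3 where formulas require it.
"""

ELEMENTARY_CHARGE = 1.602176634e-19
"""Elementary charge e (C)."""

BOLTZMANN = 1.380649e-23
"""Boltzmann constant k_B (J/K)."""

AVOGADRO = 6.02214076e23
"""Avogadro constant N_A (1/mol)."""

VACUUM_PERMITTIVITY = 8.8541878128e-12
"""Vacuum permittivity eps_0 (F/m)."""

GAS_CONSTANT = 8.314462618
"""Molar gas constant R (J/(mol K))."""

WATER_MOLARITY = 55.5
"""Molarity of liquid water (mol/L), the solvent-molarity constant of the
depletion-corrected Langmuir isotherm."""

WATER_RELATIVE_PERMITTIVITY = 78.4
"""Relative permittivity of water at 25 degC (dimensionless default)."""

STANDARD_TEMPERATURE = 298.15
"""Default absolute temperature (K) for zeta-conversion and Gibbs contexts."""
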