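"""CSV/JSON/YAML input-output and the analysis configuration schema.

One flat CSV dialect for titration data (no instrument standard exists for
SHS titrations): mandatory header, UTF-8, '.' decimal, columns
``concentration_M, intensity[, intensity_err], angle_deg, polarization``.
Rows are grouped into one curve per (angle, polarization). Reports are
schema-versioned JSON plus a human-readable table in the customary units
(K_app in 1e8 1/M, Delta G in kJ/mol).
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigError, CsvFormatError
from .types import TitrationCurve

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "curves_from_dataframe",
    "write_report",
    "load_report",
    "AnalysisConfig",
    "load_config",
]

REPORT_SCHEMA_VERSION = "1"
_REQUIRED_COLUMNS = ("concentration_M", "intensity", "angle_deg", "polarization")


# --------------------------------------------------------------------------
# titration CSV
# --------------------------------------------------------------------------

def curves_from_dataframe(df: pd.DataFrame) -> List[TitrationCurve]:
    """Group a tidy titration frame into curves, enforcing invariants with
    1-based data-row numbers in error messages."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CsvFormatError(f"missing required column(s): {', '.join(missing)}")
    for col in ("concentration_M", "intensity") + (
        ("intensity_err",) if "intensity_err" in df.columns else ()
    ):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            raise CsvFormatError(
                f"non-numeric value in column '{col}' at data row {bad[0] + 1}",
                row=int(bad[0] + 1),
            )
        df = df.assign(**{col: vals})
    curves = []
    for (angle, pol), grp in df.groupby(["angle_deg", "polarization"], sort=True):
        order = grp["concentration_M"].to_numpy()
        diffs = np.diff(order)
        if np.any(diffs <= 0):
            j = int(np.nonzero(diffs <= 0)[0][0])
            row = int(grp.index[j + 1]) + 1
            raise CsvFormatError(
                f"concentrations not strictly increasing at data row {row} "
                f"(curve angle={angle}, polarization={pol})",
                row=row,
            )
        errs = None
        if "intensity_err" in grp.columns and grp["intensity_err"].notna().all():
            errs = grp["intensity_err"].to_numpy(dtype=float)
        try:
            curves.append(
                TitrationCurve(
                    concentrations=order.astype(float),
                    intensities=grp["intensity"].to_numpy(dtype=float),
                    intensity_errors=errs,
                    scattering_angle=float(angle),
                    polarization=str(pol),
                )
            )
        except Exception as exc:
            raise CsvFormatError(f"invalid curve (angle={angle}, pol={pol}): {exc}") from exc
    if not curves:
        raise CsvFormatError("no data rows")
    return curves


def read_titration_csv(path: Union[str, Path]) -> List[TitrationCurve]:
    """Read the standard titration CSV into one curve per
    (angle, polarization) group."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    return curves_from_dataframe(df)


def write_titration_csv(curves: List[TitrationCurve], path: Union[str, Path]) -> None:
    rows = []
    for cv in curves:
        for i in range(len(cv)):
            rows.append(
                {
                    "concentration_M": repr(float(cv.concentrations[i])),
                    "intensity": repr(float(cv.intensities[i])),
                    "intensity_err": (
                        repr(float(cv.intensity_errors[i]))
                        if cv.intensity_errors is not None
                        else ""
                    ),
                    "angle_deg": cv.scattering_angle,
                    "polarization": cv.polarization,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


# --------------------------------------------------------------------------
# fit reports
# --------------------------------------------------------------------------

def _results_to_dict(results) -> dict:
    d = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "k_app_per_M": results.k_app,
        "k_app_stderr_per_M": results.k_app_stderr,
        "n_max_per_particle": results.n_max_per_particle,
        "n_max_per_particle_stderr": results.n_max_per_particle_stderr,
        "n_max_vol_M": results.n_max_vol,
        "delta_g_J_per_mol": results.delta_g,
        "delta_g_stderr_J_per_mol": results.delta_g_stderr,
        "amplitudes": results.amplitudes,
        "chisqr": results.chisqr,
        "redchi": results.redchi,
        "success": results.success,
        "seed": results.seed,
        "link": results.model.link,
        "temperature_K": results.model.temperature,
        "standard_state_M": results.model.standard_state_M,
        "number_density_per_L": results.model.number_density,
    }
    if results.bootstrap_intervals is not None:
        d["bootstrap_intervals_95"] = {
            k: list(v) for k, v in results.bootstrap_intervals.items()
        }
        d["bootstrap_stderr"] = results.bootstrap_stderr
    return d


def write_report(results, path: Union[str, Path], format: str = "json") -> None:
    """Write a fit report: machine-readable schema-versioned JSON, or a text
    table mirroring the customary column layout."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_results_to_dict(results), indent=2, sort_keys=True) + "\n")
    elif format == "text":
        k8 = results.k_app / 1e8
        dk8 = results.k_app_stderr / 1e8
        dg = -results.delta_g / 1e3
        ddg = results.delta_g_stderr / 1e3
        lines = [
            "K_app (10^8 mol^-1)\tN_max per particle\tdG_app (kJ/mol)",
            f"{k8:.3g} ± {dk8:.2g}\t"
            f"{results.n_max_per_particle:.4g} ± {results.n_max_per_particle_stderr:.2g}\t"
            f"-({dg:.1f} ± {ddg:.1f})",
            "",
            results.summary(),
        ]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("format must be 'json' or 'text'")


def load_report(path: Union[str, Path]) -> dict:
    """Read back a JSON report."""
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ConfigError(f"unsupported report schema {d.get('schema_version')!r}")
    return d


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_UNIT_SCALES = {
    # lengths -> m
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9,
    # potentials -> V
    "V": 1.0, "mV": 1e-3,
    # concentrations -> mol/L
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9,
}
_UNIT_KINDS = {
    "length": ("m", "mm", "um", "nm"),
    "potential": ("V", "mV"),
    "concentration": ("M", "mM", "uM", "nM"),
}


def _parse_quantity(value, kind: str) -> float:
    """Accept a bare number (SI / molar base unit) or a string with a unit
    suffix, e.g. '100 nm', '-42 mV', '1 mM'."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*([A-Za-zμ]+)\s*", str(value))
    if not m:
        raise ConfigError(f"cannot parse quantity {value!r}")
    num, unit = m.groups()
    unit = unit.replace("μ", "u")
    if unit not in _UNIT_KINDS[kind]:
        raise ConfigError(f"unit {unit!r} is not a {kind} unit")
    return float(num) * _UNIT_SCALES[unit]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SolutionConfig(_Section):
    temperature_K: float = 298.15
    relative_permittivity: float = 78.4
    electrolyte_valence: int = 1
    ionic_concentration_M: float = 1e-3

    @field_validator("ionic_concentration_M", mode="before")
    @classmethod
    def _conc(cls, v):
        return _parse_quantity(v, "concentration")


class ParticleConfig(_Section):
    diameter: float = Field(description="m; strings like '100 nm' accepted")
    number_density_per_L: float
    zeta_potential: Optional[float] = None
    surface_charge_C_m2: Optional[float] = None
    label: str = ""

    @field_validator("diameter", mode="before")
    @classmethod
    def _diam(cls, v):
        return _parse_quantity(v, "length")

    @field_validator("zeta_potential", mode="before")
    @classmethod
    def _zeta(cls, v):
        return None if v is None else _parse_quantity(v, "potential")


class ProteinConfig(_Section):
    name: str
    net_valence: float = -8.0


class AdsorptionConfig(_Section):
    k_app_per_M: Optional[float] = None
    n_max_per_particle: Optional[float] = None
    standard_state_M: float = 1.0
    charge_efficiency: float = 1.0


class OpticsConfig(_Section):
    fundamental_wavelength: float = 1028e-9
    refractive_index: float = 1.33
    chi2_amplitude: float = 1.0
    chi3_amplitude: float = 25.0
    link: str = "field_linear"

    @field_validator("fundamental_wavelength", mode="before")
    @classmethod
    def _wl(cls, v):
        return _parse_quantity(v, "length")


class FittingConfig(_Section):
    link: str = "field_linear"
    bootstrap_n: int = 500
    seed: Optional[int] = None
    multistart: bool = True


class SimulationConfig(_Section):
    noise_level: float = 0.02
    noise_model: str = "multiplicative_gaussian"
    replicates: int = 10
    seed: Optional[int] = None


class AnalysisConfig(_Section):
    """Validated analysis configuration; unknown keys are rejected."""

    schema_version: str = "1"
    solution: SolutionConfig = SolutionConfig()
    particle: Optional[ParticleConfig] = None
    protein: Optional[ProteinConfig] = None
    adsorption: AdsorptionConfig = AdsorptionConfig()
    optics: OpticsConfig = OpticsConfig()
    fitting: FittingConfig = FittingConfig()
    simulation: SimulationConfig = SimulationConfig()


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Load and validate a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return AnalysisConfig(**data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
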