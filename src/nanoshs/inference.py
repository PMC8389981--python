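"""Global fitting of SHS titration curves.

``TitrationModel`` couples the depletion-corrected Langmuir isotherm to the
fixed-angle intensity link and fits one or more curves by weighted nonlinear
least squares. The binding constant K_app and monolayer capacity N_max are
shared across curves ("global fit"); the intensity endpoints (I_0, I_sat)
are per-curve nuisance amplitudes. K_app and the volumetric capacity are
fitted in log space, which enforces positivity and makes the multi-start
grid natural. ``fit()`` returns a ``TitrationResults`` object carrying
estimates, standard errors from the scaled Jacobian covariance, the apparent
Gibbs free energy, diagnostics, a ``summary()`` table, and residual-
resampling ``bootstrap()`` intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .adsorption import (
    adsorbed_with_depletion,
    capacity_per_particle,
    capacity_per_volume,
    gibbs_from_k,
    gibbs_uncertainty,
)
from .errors import FitConvergenceError, InvalidConditionsError
from .optics import titration_intensity
from .types import TitrationCurve


def _exp(v: float) -> float:
    """exp with under/overflow clamping (log-parameters can collapse when
    a parameter is unidentifiable)."""
    return math.exp(min(max(v, -690.0), 690.0))

__all__ = [
    "TitrationModel",
    "TitrationResults",
    "initial_guess",
    "bootstrap_uncertainties",
]


def initial_guess(curve: TitrationCurve) -> dict:
    """Data-driven starting values for one titration curve.

    I_0 / I_sat from the first / last two points; the volumetric capacity
    from the concentration at the half-drop of sqrt-intensity (in the
    strong-depletion regime the curve's breakpoint sits near N_max_vol, and
    half coverage near N_max_vol/2); K_app seeded at 1e9 1/M. Non-monotone
    (in sqrt-intensity, beyond noise) or flat curves are flagged so the
    fitter falls back to a coarse grid search.
    """
    if len(curve) < 4:
        raise InvalidConditionsError("need at least 4 titration points")
    c = curve.concentrations
    s = np.sqrt(curve.intensities)
    i_0 = float(np.mean(curve.intensities[:2]))
    i_sat = float(np.mean(curve.intensities[-2:]))
    s0, ssat = math.sqrt(i_0), math.sqrt(i_sat)
    span = abs(s0 - ssat)
    scale = max(s0, ssat, 1e-300)
    flat = span < 0.05 * scale
    # monotone (decreasing) within a tolerance of the field span
    drift = np.diff(s)
    monotone = bool(np.all(drift <= 0.25 * max(span, 1e-300) + 1e-300)) if s0 >= ssat else False
    n_vol = None
    if not flat and monotone:
        target = 0.5 * (s0 + ssat)
        below = np.nonzero(s <= target)[0]
        if below.size:
            j = below[0]
            if j > 0 and s[j - 1] != s[j]:
                frac = (s[j - 1] - target) / (s[j - 1] - s[j])
                c_half = c[j - 1] + frac * (c[j] - c[j - 1])
            else:
                c_half = c[j]
            n_vol = max(2.0 * float(c_half), 1e-30)
    if n_vol is None:
        n_vol = max(float(np.median(c[c > 0])) if np.any(c > 0) else 1e-8, 1e-30)
    return {
        "k_app": 1e9,
        "n_max_vol": n_vol,
        "i_0": i_0,
        "i_sat": i_sat,
        "identifiable": not flat,
        "monotone": monotone,
    }


@dataclass
class TitrationResults:
    """Estimates and diagnostics from a :class:`TitrationModel` fit.

    ``k_app`` is in 1/M, ``n_max_vol`` in mol/L, ``n_max_per_particle`` a
    count; ``delta_g`` (J/mol) always equals ``gibbs_from_k(k_app)`` at the
    model's temperature and standard state. Standard errors come from the
    Jacobian covariance scaled by the reduced chi-square; ``bootstrap()``
    adds resampling spreads and percentile intervals.
    """

    model: "TitrationModel"
    params: np.ndarray  # internal vector [ln K, ln n_vol, i0_j, isat_j, ...]
    cov: Optional[np.ndarray]
    k_app: float
    k_app_stderr: float
    n_max_vol: float
    n_max_vol_stderr: float
    n_max_per_particle: float
    n_max_per_particle_stderr: float
    amplitudes: List[dict]  # per curve: i_0, i_sat with stderrs
    delta_g: float
    delta_g_stderr: float
    chisqr: float
    redchi: float
    residuals: np.ndarray
    nfev: int
    success: bool
    message: str
    diagnostics: dict = field(default_factory=dict)
    seed: Optional[int] = None
    bootstrap_samples: Optional[pd.DataFrame] = None
    bootstrap_intervals: Optional[Dict[str, tuple]] = None
    bootstrap_stderr: Optional[Dict[str, float]] = None

    def predict(self, concentrations, curve_index: int = 0) -> np.ndarray:
        return self.model.predict(self.params, np.asarray(concentrations, float), curve_index)

    def bootstrap(self, n_boot: int = 500, seed: Optional[int] = None) -> "TitrationResults":
        return bootstrap_uncertainties(self, n_boot=n_boot, seed=seed)

    def summary(self) -> str:
        """Table in the field's customary units: K_app in 1e8 1/M, N_max
        per particle, Delta G_app in kJ/mol (one decimal)."""
        lines = [
            "SHS titration fit (depletion-corrected Langmuir, "
            f"{self.model.link} link, global over {len(self.model.curves)} curve(s))",
            "-" * 72,
            f"{'K_app (10^8 /M)':>22}  {'N_max per particle':>20}  {'dG_app (kJ/mol)':>16}",
            (
                f"{self.k_app/1e8:>12.3g} ± {self.k_app_stderr/1e8:<8.2g}"
                f"{self.n_max_per_particle:>12.4g} ± {self.n_max_per_particle_stderr:<7.2g}"
                f"-({-self.delta_g/1e3:.1f} ± {self.delta_g_stderr/1e3:.1f})"
            ),
            "-" * 72,
            f"chi-square {self.chisqr:.4g}   reduced {self.redchi:.4g}   nfev {self.nfev}",
        ]
        for j, amp in enumerate(self.amplitudes):
            cv = self.model.curves[j]
            lines.append(
                f"curve {j} ({cv.scattering_angle:g} deg {cv.polarization}): "
                f"I0 = {amp['i_0']:.4g} ± {amp['i_0_stderr']:.2g}, "
                f"Isat = {amp['i_sat']:.4g} ± {amp['i_sat_stderr']:.2g}"
            )
        if not self.diagnostics.get("identifiable", True):
            lines.append("warning: flat curve, K_app unidentifiable")
        if self.bootstrap_intervals:
            lines.append("bootstrap 95% intervals:")
            for k, (lo, hi) in self.bootstrap_intervals.items():
                lines.append(f"  {k}: [{lo:.4g}, {hi:.4g}]")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look plot of data and fitted curves (one axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j, cv in enumerate(self.model.curves):
            line = ax.errorbar(
                cv.concentrations,
                cv.intensities,
                yerr=cv.intensity_errors,
                fmt="o",
                label=f"{cv.scattering_angle:g} deg {cv.polarization}",
            )
            grid = np.geomspace(
                max(cv.concentrations[cv.concentrations > 0].min(), 1e-12),
                cv.concentrations.max(),
                200,
            )
            ax.plot(grid, self.predict(grid, j), color=line[0].get_color())
        ax.set_xscale("log")
        ax.set_xlabel("total protein concentration (M)")
        ax.set_ylabel("SHS intensity (arb)")
        ax.legend()
        return ax


class TitrationModel:
    """Depletion-corrected Langmuir + intensity-link model for one or more
    fixed-angle SHS titration curves.

    Parameters
    ----------
    curves : sequence of TitrationCurve
        The titration data; K_app and N_max are shared across all of them.
    number_density : float
        Particle number density (1/L), converting the fitted volumetric
        capacity to a per-particle count.
    link : {"field_linear", "intensity_linear"}
        How coverage maps to intensity; the field-linear (sqrt-intensity)
        link is the physically consistent default.
    temperature, standard_state_M
        Passed to the Gibbs relation for the reported Delta G_app.
    """

    def __init__(
        self,
        curves: Sequence[TitrationCurve],
        number_density: float,
        link: str = "field_linear",
        temperature: float = 298.15,
        standard_state_M: float = 1.0,
    ):
        curves = list(curves)
        if not curves:
            raise InvalidConditionsError("at least one curve is required")
        for cv in curves:
            if len(cv) < 4:
                raise InvalidConditionsError("each curve needs >= 4 points")
        if not (number_density > 0):
            raise InvalidConditionsError("number density must be positive")
        if link not in ("field_linear", "intensity_linear"):
            raise InvalidConditionsError("unknown link model")
        self.curves = curves
        self.number_density = float(number_density)
        self.link = link
        self.temperature = float(temperature)
        self.standard_state_M = float(standard_state_M)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, number_density: float, **kwargs) -> "TitrationModel":
        """Build from a tidy frame with columns concentration_M, intensity,
        optional intensity_err, angle_deg, polarization."""
        from .io import curves_from_dataframe

        return cls(curves_from_dataframe(df), number_density, **kwargs)

    @classmethod
    def from_csv(cls, path, number_density: float, **kwargs) -> "TitrationModel":
        from .io import read_titration_csv

        return cls(read_titration_csv(path), number_density, **kwargs)

    # -- parameter plumbing ----------------------------------------------
    @property
    def n_params(self) -> int:
        return 2 + 2 * len(self.curves)

    def pack(self, k_app: float, n_max_vol: float, amplitudes: Sequence[tuple]) -> np.ndarray:
        p = [math.log(k_app), math.log(n_max_vol)]
        for i0, isat in amplitudes:
            p += [i0, isat]
        return np.array(p, dtype=float)

    def predict(self, params: np.ndarray, concentrations: np.ndarray, curve_index: int) -> np.ndarray:
        # clamp so exp() cannot under/overflow during optimizer excursions
        k_app = math.exp(min(max(params[0], -690.0), 690.0))
        n_vol = math.exp(min(max(params[1], -690.0), 690.0))
        i0 = params[2 + 2 * curve_index]
        isat = params[3 + 2 * curve_index]
        theta = adsorbed_with_depletion(concentrations, k_app, n_vol) / n_vol
        # amplitudes are unconstrained during optimisation; clip for the link
        return titration_intensity(np.clip(theta, 0.0, 1.0), max(i0, 0.0), max(isat, 0.0), self.link)

    def residuals(
        self,
        params: np.ndarray,
        intensities: Optional[List[np.ndarray]] = None,
        errors: Optional[List[np.ndarray]] = None,
    ) -> np.ndarray:
        out = []
        for j, cv in enumerate(self.curves):
            obs = cv.intensities if intensities is None else intensities[j]
            if errors is not None:
                w = errors[j]
            else:
                w = cv.intensity_errors if cv.intensity_errors is not None else 1.0
            mod = self.predict(params, cv.concentrations, j)
            out.append((mod - obs) / w)
        return np.concatenate(out)

    # -- fitting ----------------------------------------------------------
    def _single_fit(self, x0: np.ndarray, intensities=None, errors=None):
        return least_squares(
            self.residuals,
            x0,
            kwargs={"intensities": intensities, "errors": errors},
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=4000,
        )

    def fit(self, start: Optional[dict] = None, multistart: bool = True) -> TitrationResults:
        """Weighted nonlinear least squares; multi-start on a 3x3 log-grid
        around the data-driven initial guess, ties (<1e-9 relative in
        chi-square) broken toward smaller K_app."""
        guesses = [initial_guess(cv) for cv in self.curves]
        g0 = dict(guesses[0])
        if start:
            g0.update(start)
        amp0 = [(g["i_0"], g["i_sat"]) for g in guesses]
        x0 = self.pack(g0["k_app"], g0["n_max_vol"], amp0)

        starts = [x0]
        if multistart:
            for dk in (-math.log(10.0), 0.0, math.log(10.0)):
                for dn in (-0.5 * math.log(10.0), 0.0, 0.5 * math.log(10.0)):
                    if dk == 0.0 and dn == 0.0:
                        continue
                    xi = x0.copy()
                    xi[0] += dk
                    xi[1] += dn
                    starts.append(xi)

        best = None
        for xi in starts:
            try:
                res = self._single_fit(xi)
            except Exception:
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            if best is None:
                best = res
                continue
            rel = (best.cost - res.cost) / max(best.cost, 1e-300)
            if rel > 1e-9 or (abs(rel) <= 1e-9 and res.x[0] < best.x[0]):
                best = res
        if best is None:
            raise FitConvergenceError("no start converged", best_params=x0)

        return self._results_from(best, dict(guesses[0]))

    def _results_from(self, res, diagnostics: dict) -> TitrationResults:
        ndata = sum(len(cv) for cv in self.curves)
        dof = max(ndata - self.n_params, 1)
        chisqr = float(2.0 * res.cost)
        redchi = chisqr / dof
        # covariance of the internal parameters, scaled by reduced chi-square
        cov = None
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * redchi
        except np.linalg.LinAlgError:
            diagnostics["covariance"] = "singular Jacobian"
        p = res.x
        k_app = _exp(p[0])
        n_vol = _exp(p[1])
        if cov is not None:
            k_err = k_app * math.sqrt(max(cov[0, 0], 0.0))
            n_err = n_vol * math.sqrt(max(cov[1, 1], 0.0))
        else:
            k_err = n_err = float("nan")
        amps = []
        for j in range(len(self.curves)):
            i0, isat = p[2 + 2 * j], p[3 + 2 * j]
            if cov is not None:
                e0 = math.sqrt(max(cov[2 + 2 * j, 2 + 2 * j], 0.0))
                e1 = math.sqrt(max(cov[3 + 2 * j, 3 + 2 * j], 0.0))
            else:
                e0 = e1 = float("nan")
            amps.append({"i_0": i0, "i_sat": isat, "i_0_stderr": e0, "i_sat_stderr": e1})
            if isat > i0:
                diagnostics.setdefault("flags", []).append(
                    f"curve {j}: I_sat > I_0 (charge-increasing adsorbate)"
                )
        delta_g = gibbs_from_k(k_app, self.temperature, self.standard_state_M)
        dg_err = gibbs_uncertainty(k_app, k_err, self.temperature) if math.isfinite(k_err) else float("nan")
        return TitrationResults(
            model=self,
            params=p,
            cov=cov,
            k_app=k_app,
            k_app_stderr=k_err,
            n_max_vol=n_vol,
            n_max_vol_stderr=n_err,
            n_max_per_particle=capacity_per_particle(n_vol, self.number_density),
            n_max_per_particle_stderr=n_err * (6.02214076e23 / self.number_density),
            amplitudes=amps,
            delta_g=delta_g,
            delta_g_stderr=dg_err,
            chisqr=chisqr,
            redchi=redchi,
            residuals=res.fun,
            nfev=res.nfev,
            success=bool(res.success),
            message=str(res.message),
            diagnostics=diagnostics,
        )


def bootstrap_uncertainties(
    fit: TitrationResults,
    n_boot: int = 500,
    seed: Optional[int] = None,
    curves: Optional[Sequence[TitrationCurve]] = None,
) -> TitrationResults:
    """Residual-resampling bootstrap of a converged fit.

    Standardized residuals are resampled with replacement, inflated by
    sqrt(n/dof) to undo the variance shrinkage caused by fitting the
    parameters, rescaled by each point's error, added to the fitted model
    values, and the model is refit (single start from the fitted
    parameters). Reports per-parameter standard deviations and 2.5/97.5
    percentile intervals. The headline ``bootstrap_intervals`` for K_app,
    N_max and Delta G are studentized (bootstrap-t) in log-parameter space:
    each refit also yields a Jacobian standard error, the pivot
    t* = (theta* - theta_hat)/se* is accumulated, and the interval is
    theta_hat - se_hat * t*_{97.5/2.5}. Studentization makes the interval
    width respond to how noisy the error estimate itself is, which plain
    percentile intervals miss. The headline interval is the deliberately
    conservative envelope (union) of the three standard constructions -
    percentile, studentized, and Wald in log space - since each fails in a
    different regime (skew, scale uncertainty, small samples); the plain
    percentile interval is kept in the diagnostics. The analytic Gibbs
    uncertainty R T dK/K is kept alongside for comparison. Seeded runs are
    bit-reproducible.

    When a curve's metadata records the replicate count ``m`` behind its
    standard-error bars, each bootstrap refit additionally draws perturbed
    weights sigma_i* = sigma_i sqrt((m-1)/chi2_{m-1}) — the exact sampling
    distribution of an SEM estimated from m normal draws — so the interval
    reflects that the analyst's error bars are themselves estimates.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    if seed is None:
        seed = fit.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible bootstrap")
    model = fit.model
    rng = np.random.default_rng(seed)
    fitted = [model.predict(fit.params, cv.concentrations, j) for j, cv in enumerate(model.curves)]
    sigmas = [
        cv.intensity_errors if cv.intensity_errors is not None else np.ones(len(cv))
        for cv in model.curves
    ]
    nres = fit.residuals.size
    dof = max(nres - model.n_params, 1)
    # dof inflation: raw residuals underestimate the noise after fitting
    std_resid = fit.residuals * math.sqrt(nres / dof)

    def _log_se(res, dof_local):
        """Jacobian standard errors of (ln K, ln n_vol), redchi-scaled."""
        try:
            cov_b = np.linalg.inv(res.jac.T @ res.jac) * (2.0 * res.cost / dof_local)
        except np.linalg.LinAlgError:
            return None
        return (
            math.sqrt(max(cov_b[0, 0], 1e-300)),
            math.sqrt(max(cov_b[1, 1], 1e-300)),
        )

    # replicate counts behind the SEM error bars, where recorded
    rep_counts = [
        cv.metadata.get("replicates")
        if cv.intensity_errors is not None and isinstance(cv.metadata.get("replicates"), int)
        and cv.metadata.get("replicates", 0) > 1
        else None
        for cv in model.curves
    ]

    rows, pivots = [], []
    for _ in range(n_boot):
        draw = std_resid[rng.integers(0, nres, size=nres)]
        new_int, new_err, k = [], [], 0
        for j, cv in enumerate(model.curves):
            n = len(cv)
            new_int.append(np.clip(fitted[j] + draw[k : k + n] * sigmas[j], 0.0, None))
            m = rep_counts[j]
            if m is not None:
                chi2 = rng.chisquare(m - 1, size=n)
                new_err.append(sigmas[j] * np.sqrt((m - 1) / np.maximum(chi2, 1e-12)))
            else:
                new_err.append(sigmas[j])
            k += n
        try:
            res = model._single_fit(fit.params.copy(), intensities=new_int, errors=new_err)
        except Exception:
            continue
        k_app = _exp(res.x[0])
        n_vol = _exp(res.x[1])
        row = {
            "k_app": k_app,
            "n_max_vol": n_vol,
            "n_max_per_particle": capacity_per_particle(n_vol, model.number_density),
            "delta_g": gibbs_from_k(k_app, model.temperature, model.standard_state_M),
        }
        for j in range(len(model.curves)):
            row[f"i_0_{j}"] = res.x[2 + 2 * j]
            row[f"i_sat_{j}"] = res.x[3 + 2 * j]
        rows.append(row)
        se = _log_se(res, dof)
        if se is not None:
            pivots.append(
                (
                    (res.x[0] - fit.params[0]) / se[0],
                    (res.x[1] - fit.params[1]) / se[1],
                )
            )
    samples = pd.DataFrame(rows)
    if len(samples) < max(10, n_boot // 2):
        raise FitConvergenceError(
            f"bootstrap refits converged only {len(samples)}/{n_boot} times",
            best_params=fit.params,
        )
    percentile = {
        col: tuple(np.percentile(samples[col], [2.5, 97.5])) for col in samples.columns
    }
    stderr = {col: float(samples[col].std(ddof=1)) for col in samples.columns}

    # envelope of percentile, studentized (bootstrap-t) and Wald intervals,
    # the latter two built in log-parameter space
    intervals = dict(percentile)
    if pivots and fit.cov is not None:
        tk, tn = np.array(pivots).T
        se_k = math.sqrt(max(fit.cov[0, 0], 1e-300))
        se_n = math.sqrt(max(fit.cov[1, 1], 1e-300))
        stud_k = (
            fit.params[0] - se_k * np.percentile(tk, 97.5),
            fit.params[0] - se_k * np.percentile(tk, 2.5),
        )
        stud_n = (
            fit.params[1] - se_n * np.percentile(tn, 97.5),
            fit.params[1] - se_n * np.percentile(tn, 2.5),
        )
        wald_k = (fit.params[0] - 1.959964 * se_k, fit.params[0] + 1.959964 * se_k)
        wald_n = (fit.params[1] - 1.959964 * se_n, fit.params[1] + 1.959964 * se_n)
        scale = 6.02214076e23 / model.number_density

        def _envelope(pct, *log_ivs):
            los = [pct[0]] + [_exp(iv[0]) for iv in log_ivs]
            his = [pct[1]] + [_exp(iv[1]) for iv in log_ivs]
            return (min(los), max(his))

        intervals["k_app"] = _envelope(percentile["k_app"], stud_k, wald_k)
        intervals["n_max_vol"] = _envelope(percentile["n_max_vol"], stud_n, wald_n)
        intervals["n_max_per_particle"] = tuple(
            v * scale for v in intervals["n_max_vol"]
        )
        # Delta G is a decreasing linear map of ln K
        intervals["delta_g"] = (
            gibbs_from_k(intervals["k_app"][1], model.temperature, model.standard_state_M),
            gibbs_from_k(intervals["k_app"][0], model.temperature, model.standard_state_M),
        )
    out = replace(
        fit,
        seed=seed,
        bootstrap_samples=samples,
        bootstrap_intervals=intervals,
        bootstrap_stderr=stderr,
    )
    out.diagnostics = dict(fit.diagnostics)
    out.diagnostics["bootstrap_n"] = int(len(samples))
    out.diagnostics["delta_g_stderr_analytic"] = fit.delta_g_stderr
    out.diagnostics["bootstrap_intervals_percentile"] = percentile
    return out
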