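# Methods

`nanoshs` analyses label-free nonresonant second-harmonic-scattering (SHS)
titrations of proteins onto charged nanoparticles. This note records the
models, their assumptions, the numerical choices, and what the synthetic
data do and do not emulate.

## Electrostatics of the particle surface

The diffuse double layer around a sphere of radius `R` in a symmetric z:z
electrolyte is characterised by the inverse Debye length

    kappa^2 = 2 N_A e^2 z^2 (1000 c) / (eps0 eps_r k_B T),    c in mol/L.

Charge–potential relations implemented:

- **Planar (Grahame)**: `sigma = (2 eps0 eps_r kappa k_B T / (z e))
  sinh(z e Phi / 2 k_B T)`, with the closed-form `asinh` inverse.
- **Sphere (Ohshima–Healy–White)**: the same prefactor times `sinh(y/2)`
  times a curvature bracket
  `[1 + 2/(kR cosh^2(y/4)) + 8 ln cosh(y/4)/(kR^2 sinh^2(y/2))]^(1/2)`,
  `y = z e Phi / k_B T`. The bracket's `y -> 0` limit is taken analytically
  (a series below `|y| < 1e-3`), so the small-potential behaviour is the
  exact linear sphere capacitance `eps0 eps_r (1 + kR)/R` and the
  `kR -> inf` limit is Grahame. The relation is odd and strictly monotone.
- **Sphere inverse**: no analytic inverse exists; we bracket from the
  linear (Debye–Hückel) estimate by geometric expansion and polish with
  Brent's method, verifying a relative charge residual below 1e-10.
- **Linearised map**: the least-squares slope of the sphere relation over a
  symmetric window (default ±150 mV; odd symmetry forces a zero intercept),
  for converting intensity-derived fields to charge at fixed conditions.

Zeta potentials are treated as equal to the surface potential when
converting; this is an approximation (slip plane at the surface) and is
flagged in output metadata. Defaults: `eps_r = 78.4`, `T = 298.15 K`
(zeta-conversion conditions); both configurable. Mixed/asymmetric
electrolytes, Stern layers and charge regulation are out of scope.

## Adsorption model

Monolayer (Langmuir) adsorption with bulk depletion: at the particle number
densities used, the volumetric site capacity `N_max_vol` (mol/L of binding
sites) is comparable to the total protein concentration, so binding
depletes the free pool. The coverage solves

    adsorbed = N_max_vol * K c_free / (1 + K c_free),
    c_free   = c_total - adsorbed,

a quadratic whose physical root we evaluate in the cancellation-free form
`adsorbed = 2 c n / (S + sqrt(S^2 - 4 c n))`, `S = c + n + 1/K`. This stays
accurate at the near-degenerate discriminant (`c_total ≈ N_max_vol`,
`K c >> 1`), which is exactly the stoichiometric-titration regime of
interest; it is verified against a fixed-point bisection oracle to 1e-10
over six decades in each variable.

`K_app` is parameterised so that the half-saturation *free* concentration
is `1/K_app` (units 1/M). The solvent-molarity constant of the isotherm is
absorbed into this parameterisation. The apparent Gibbs free energy uses

    dG_app = -R T ln(K_app * c0),   c0 = 1 M (default), T = 298.15 K,

because this convention reproduces the internally consistent (K, dG) pairs
of the reference fits to <= 0.15 kJ/mol; the 55.5 M solvent-molarity
standard state is available via `standard_state_M`. First-order uncertainty
propagation gives `d(dG) = R T dK/K`.

Only the ratio `K = k_a/k_d` is identifiable from equilibrium titrations;
rates, multilayers, cooperativity and competitive (Vroman) adsorption are
out of scope.

**Charge update on adsorption.** Experimentally the magnitude of the
surface potential falls on protein adsorption even for like-charged
proteins (e.g. -42 mV to -31 mV for HSA on plain polystyrene): the protein
arrives dressed in counterions and effectively screens the surface. The
model is linear in coverage,

    sigma(theta) = sigma_bare - sign(sigma_bare) * eta * theta
                   * N_max |z_p| e / (pi D^2),

with a screening efficiency `eta in [0, 1]` because the measurement does
not resolve the microscopic charge bookkeeping. `eta` can be calibrated
from bare/saturated zeta endpoints (`~0.145` for the HSA/plain-PS pair);
the uncalibrated default is 1, which is logged as a caveat since it can
overshoot neutrality.

## SHS forward model

The detected second-harmonic field from one particle is the coherent sum of
a surface second-order term and a bulk third-order term sourced by solvent
molecules aligned/polarised in the static double-layer field,

    I(theta) ∝ n_p |w(theta)| ^2 |chi2 F_surf(qR)
               + e^{i phase} chi3 Phi0 F3(kR, qR)|^2,

with `q = (8 pi n / lambda) sin(theta/2)` (dispersionless medium,
`|k_2w| = 2|k_w|`), incoherent over particles (linear in number density
`n_p`).

- **Surface form factors**: sphere-surface integrals of `exp(i q.r)` times
  normal-projection powers 0–3, in closed spherical-Bessel form
  (`4 pi R^2 j0`, `4 pi R^2 i j1`, `(j0 - 2 j2)/3`, `i(3 j1 - 2 j3)/5`
  times the area); all verified against direct quadrature to 1e-6.
- **Bulk chi3 form factor**: the volume integral of `exp(i q.r)` weighted
  by the radial field of the linearised profile
  `Phi(r) = Phi0 (R/r) exp(-kappa(r-R))` reduces to a single radial
  integral `4 pi i Phi0 R^2 ∫ (1 + kR x) e^{-kR(x-1)} j1(qR x) dx`,
  evaluated adaptively and truncated at `20/kappa` beyond the surface
  (relative tail below e^-20); verified against nested 2-D quadrature to
  1e-4. Strictly linear in `Phi0`. The nonlinear (Poisson–Boltzmann)
  profile is out of scope, consistent with the diffuse-layer assumption.
- **Polarization channels**: the full tensor algebra is reduced to scalar
  angular envelopes, `w_ppp = sin(theta)` and
  `w_pss = sin(theta) cos(theta/2)`, both vanishing in the exact forward
  direction. This is the coarsest reduction that preserves the observable
  phenomenology (interior maximum, screening-induced peak shift); full 2w
  polarimetry, Mie corrections and resonant enhancement are out of scope.
  Quantitative peak positions and shift magnitudes depend on the
  wavelength, refractive index and chi3/chi2 ratio, so only their signs and
  monotonicity are asserted.

Defaults: `lambda = 1028 nm`, `n = 1.33`, `chi2 = 1`, `chi3 = 25 /V`
(bulk-dominated at low ionic strength, as appropriate for nonresonant SHS
where the signal originates mainly from field-aligned water), relative
phase 0, hyper-Rayleigh water background 0. All configurable.

**Fixed-angle titration link.** At fixed angle and ionic strength the form
factors are constants and the *field* tracks the surface charge, which the
linearised charge–potential map makes linear in coverage. Hence the default
link `sqrt(I) = sqrt(I_0) - (sqrt(I_0) - sqrt(I_sat)) theta` ("field
linear", convex in theta). The affine `intensity_linear` link is kept for
sensitivity analysis; the headline derived quantities (dG from K, areas
from N_max) are robust to the choice. `I_sat > I_0` (charge-increasing
adsorbate) is allowed and flagged.

## Fitting

`TitrationModel.fit()` minimises the weighted sum of squares
`sum[(I_obs - I_model)^2 / sigma_I^2]` over one or more curves with
`(ln K_app, ln N_max_vol)` shared globally and `(I_0, I_sat)` per curve.
Log-parameterisation enforces positivity. Unweighted (`sigma_I = 1`) when
no errors are supplied.

- **Initial guess**: `I_0`/`I_sat` from the first/last two points;
  `N_max_vol` from twice the concentration at the half-drop of
  sqrt-intensity (the depletion breakpoint); `K_app` seeded at 1e9 /M.
  Flat curves are flagged unidentifiable; non-monotone curves fall back to
  a median-concentration seed and the multi-start grid.
- **Multi-start**: a 3x3 grid (±1 decade in K, ±0.5 decade in N) around the
  guess; best chi-square wins, ties (<1e-9 relative) resolved toward
  smaller K_app. Levenberg–Marquardt, tolerances 1e-12.
- **Standard errors**: Jacobian covariance scaled by the reduced
  chi-square. `dG` and its analytic uncertainty follow from `K_app` by
  construction.

**Bootstrap.** Residual resampling: standardised residuals are resampled
with replacement, inflated by `sqrt(n/dof)` (raw residuals underestimate
the noise after fitting), rescaled by each point's error and added to the
fitted values; the model is refit from the fitted parameters. When a
curve's metadata records the replicate count `m` behind its standard-error
bars, each refit draws perturbed weights
`sigma* = sigma sqrt((m-1)/chi2_{m-1})` — the exact sampling distribution
of an SEM estimated from `m` normal draws — so the intervals reflect that
the error bars are themselves estimates; without that term the bootstrap
world has fixed weights and visibly under-covers. The reported 95% interval
for `K_app`, `N_max` and `dG` is the deliberately conservative envelope of
the three standard constructions — percentile, studentized (bootstrap-t,
log-parameter space) and Wald (log space) — because each fails in a
different regime (skew, noisy error scale, small samples); plain
percentiles and standard deviations are reported alongside. Bootstrap runs
are seeded and bit-reproducible; the default is 500 resamples.

In the strong-depletion regime the titration constrains `N_max` tightly
(the breakpoint) but `K_app` only weakly (the curve is insensitive to `K`
once `K c >> 1`), so `K` intervals are expected to span decades; this is a
property of the experiment, not of the optimiser.

## Synthetic data

The generator emulates fixed-angle titrations in the strong-binding /
strong-depletion regime and angle-resolved screening pairs. Each point is
the mean of `replicates` (default 10) draws with multiplicative Gaussian
noise (default 2% relative — chosen once to match the visible scatter of
such measurements), and the recorded error is the standard error of that
mean, mirroring the practice of averaging each point over at least ten
acquisitions. The default grid is 15 log-spaced points between 1 nM and
10 uM, straddling the depletion breakpoint of every preset. Nine presets
carry the reference (K_app, N_max) parameter sets for the six
protein/functionalisation combinations on 100 nm particles and the
100/200/500 nm HSA size series at number densities 4.55e14, 1.31e13 and
1.81e12 per litre. Intensity endpoints default to `I_0 = 1` and
`I_sat = (31/42)^2` (the measured bare/saturated zeta ratio under the
field-linear link). Protein net valences: HSA -8 (measured at pH 6.6);
Fbg -10 and Tf -2 are isoelectric-point-based defaults affecting only the
optional charge-update model.

What the generator does **not** emulate: instrument drift, stirring and
sedimentation, aggregation (e.g. by near-neutral proteins), polydispersity,
deviations from Langmuir kinetics (cooperativity, multilayers, exchange),
and correlated or non-Gaussian noise. Passing recovery tests therefore
demonstrate the correctness and calibration of the pipeline under its own
statistical assumptions, not robustness to every feature of real
measurements.

## Problem sizes and determinism

Validation uses problem sizes chosen to make the full suite quick on a
single CPU: Monte-Carlo recovery runs 100 seeded replicates of the
two-angle HSA/100 nm scenario with 200 bootstrap resamples each (the
package default for a single analysis remains 500); oracle-equivalence
grids cover 6–7 points per decade-spanning axis. All stochastic paths take
explicit seeds (`numpy.random.default_rng`) and are bit-reproducible.

## Known limitations

- Zeta = surface potential is an approximation; at 1 mM the slip plane
  sits ~1 nm outside the surface, so converted charge densities are lower
  bounds. The sphere conversions for the 200/500 nm particles agree with
  independently quoted values only to ~10%.
- The scalar polarization channels reproduce trends, not absolute pattern
  shapes; peak positions shift with the unreported optical constants.
- The Langmuir picture can underestimate binding constants for proteins
  with complex adsorption kinetics; `K_app` and `dG_app` are apparent
  quantities.
- The charge-update efficiency `eta` is phenomenological; its default of 1
  can overshoot charge neutrality at full coverage.
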