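# Methods

## Model

The liquid phase is a mixture of 18-carbon fatty acids lumped by number of
double bonds: C18:3 (A), C18:2 (B), C18:1 (C), C18:0 (D), described by
relative molar fractions `X_i` with `ΣX_i = 1`. Hydrogenation over the
Lindlar catalyst proceeds as the irreversible cascade A → B → C → D; shunt
(multi-bond) co-hydrogenations, positional/geometric isomerization and
non-catalytic routes are excluded by hypothesis, and the catalyst surface
is ideal in the Langmuir sense. The reactor is an isothermal batch vessel
with continuous H₂ insufflation at a regulated set-point, so H₂ partial
pressure is a per-test constant and the mass balances reduce to
`dX_i/dt = r_i(X)`. Film and intraparticle transport limitations are
assumed absent (intrinsic regime); there is no dissolved-H₂ balance.

Six surface mechanisms are implemented, labelled `a`–`f`. They differ in
whether H₂ adsorbs at all (Eley–Rideal in `c`), whether its adsorption is
dissociative (`a`, `b`; Horiuti–Polanyi type with semihydrogenated
intermediates) or molecular (`d`, `e`, `f`; an *escamotage* for pairwise
addition of adjacent adsorbed H), and whether H₂ competes with the fatty
acids for sites (`b`, `e`, competitive; `a`, `d`, dedicated sites; `f`,
both channels). Quasi-equilibrated adsorption/desorption steps carry
van 't Hoff equilibrium constants `K_m`; irreversible surface reactions
carry Arrhenius rate constants `k_n`; the pseudo-steady state is applied to
surface intermediates. Only the resulting closed-form rate laws are
evaluated at run time — surface coverages never appear as state variables.
All six laws share the cascade structure `r = (-t1, t1-t2, t2-t3, t3)`,
which makes `Σ r_i = 0` hold to machine precision by construction, and all
denominators are ≥ 1 for non-negative fractions, so rates are always
finite.

Both constant families are centred at a reference temperature:

```
k_n = A_n exp(-Ea_n/R (1/T - 1/Tmean)),   K_m = B_m exp(-ΔH_m/R (1/T - 1/Tmean))
```

so each pre-exponential *is* the constant's value at `Tmean`, which
decorrelates the two parameters of each pair in the regression. `Tmean`
defaults to 433.15 K, the arithmetic mean of the campaign's nominal test
temperatures (120, 180, 180 °C); it is configurable because the convention,
not the physics, fixes it.

### Units

| quantity | unit | note |
| --- | --- | --- |
| time | min | rate pre-exponentials are per minute |
| temperature | K internally; test specs take °C | nominal per test, ±5 °C band ignored |
| H₂ pressure | bar internally; test specs take MPa (×10) | K1's pre-exponential is per bar |
| energies | kJ/mol | converted to J/mol against R = 8.314 J mol⁻¹ K⁻¹ |
| compositions | mole fraction | dimensionless |

### Parameter counts

One (pre-exponential, energy) pair per constant appearing in the printed
rate law: `a`, `b` → 20, `c` → 18, `d`, `e` → 14, `f` → 22. A transposed
row in one literature tabulation lists 14 for `c` and 18 for `e`; the
structural counts above follow from the rate-law expressions themselves
and are what `parameter_dimension` returns.

## Reference parameter set

`data/scheme_d_reference.yaml` ships the mechanism-d values regressed for
the canola-oil campaign this package models (B1 = 0.116 bar⁻¹,
ΔH1 = −101 kJ/mol; B2 = 11.2, ΔH2 = −0.761; B3 = 71.3, ΔH3 = −0.287;
B7 = 3.27, ΔH7 = +26.0; A4 = 0.122, Ea4 = 57.3; A5 = 0.0141, Ea5 = 55.2;
A6 = 0.0128, Ea6 = 64.3). Two source inconsistencies are resolved as
follows: the tabulated Ea5 of "5.52·10⁺⁰⁴ kJ/mol" is physically impossible
and is read as J/mol (55.2 kJ/mol, consistent with the prose value ~55);
and the prose values of 1/K7 (4.8 at 120 °C, 1.7 at 180 °C) are mutually
consistent in ratio but off from B7 = 3.27 by a constant factor, so 1/K7
is never used as a reference quantity — K2 and K3 are.

## Batch simulation

`solve_ivp` with LSODA (stiffness-switching), defaults rtol = 1e-8,
atol = 1e-10. The t = 0 sample is pinned to the exact initial state (the
solver's dense interpolation can wobble in the last bit). Trial states that
dip below zero by round-off are clamped to zero before rate evaluation;
violations beyond 1e-9 are errors. Mole-fraction drift beyond 1e-6 at any
reported time raises an integration error. Each integration carries an
rhs-call budget (default 500 000; 20 000 during fitting) so that
pathological parameter draws register as infeasible points instead of
stalling.

## Global regression

The objective is the unweighted global sum of squared residuals over all
tests, sample times and components, including t = 0 (which contributes
zero by construction, since each test's initial composition is taken from
its t = 0 observation rather than regressed). Optimization uses
trust-region-reflective bounded least squares over a transformed vector:
log10 of each pre-exponential (bounds 1e-6 to 1e6 in natural units) and
linear energies (Ea ∈ [0, 300], ΔH ∈ [−300, 300] kJ/mol). Multistart
(default 20 starts, seed 42) draws pre-exponentials log-uniformly and
energies uniformly; explicit warm starts can be supplied.

Numerical choices that matter:

- **Finite-difference step.** The residual Jacobian uses forward
  differences with a relative step of 1e-4 during exploration and 1e-5
  during polish — deliberately far above the integrator tolerance, because
  steps near sqrt(machine-eps) measure ODE-solver noise rather than
  sensitivity and derail the trust region.
- **Trust-region scaling.** `x_scale="jac"` (column norms of the
  Jacobian) rescales the search space per iteration; with the mixed
  log-pre-exponential/energy parameterization this is what lets the
  optimizer traverse the long, curved, nearly flat valleys of these rate
  laws instead of terminating in them.
- **Two integrator tolerances.** Exploration runs at rtol 1e-7/atol 1e-9
  for speed; the winning start is re-optimized ("polished") and all
  reported statistics, trajectories and uncertainties are computed at the
  reference tolerance rtol 1e-8/atol 1e-10.
- **Evaluation cap.** Each start is limited to 400 residual evaluations;
  infeasible points (integration failure or budget hit) return a large
  flat penalty so the optimizer backs away.
- **Early stop.** Once a start attains SSR ≤ 1e-12 (an essentially exact
  fit) the remaining starts are skipped — they cannot improve on it. The
  diagnostics record both the requested and the executed number of
  starts. Noisy data never trigger this.
- **Exact identities.** SSR_global is finalized as the sum of the
  per-(component, test) table, making the additivity and
  R² = 1 − SSR/SST identities exact; both are asserted on construction of
  every `FitResult`.

Parameter uncertainty is the linearized (Gauss–Newton) covariance
`s² (JᵀJ)⁻¹` with `s² = SSR/(N − p)` and J assembled by forward differences
in natural parameter space at the optimum. The method is an approximation
reported as such; eigendirections of JᵀJ below 1e-12 of the largest
eigenvalue are treated as unidentifiable and the affected parameters get
infinite standard deviation with a warning rather than an exception. With
data at only two temperatures and three pressures several directions of
the 14-parameter mechanism-d model are sloppy, so recovery claims in the
tests are about *predictions* (trajectories), never elementwise parameter
values.

## Mechanism discrimination

Fits on the same dataset (enforced via a dataset fingerprint) are ranked
by R²; fits within 0.005 of each other are statistically comparable and
the one with fewer parameters wins (Occam's razor). The comparison emits a
mechanism-summary table (rate-law id, parameter count, SSR_global, R²) and
a per-(mechanism, test) grid of component residual sums.

## Synthetic campaign

`default_experiment_suite()` mirrors the supported campaign: Test 3
(120 °C, 0.8 MPa, 6 h), Test 4 (180 °C, 0.4 MPa, 6 h), Test 5 (180 °C,
1.2 MPa, 5 h), sampled every 30 min from t = 0. The initial composition
(0.10, 0.22, 0.66, 0.02) is a canola-like C18 lump. Observations are the
mechanism-d trajectories under the reference parameters plus additive
i.i.d. Gaussian noise per fraction (σ = 0.005 absolute, a typical GC
repeatability), clipped at zero and renormalized to the simplex —
renormalization slightly correlates the per-sample noise, the price of
keeping generated data valid compositions. The noise is unbiased before
renormalization; with σ = 0 the generator returns the noiseless
predictions bit-exactly.

What the generator does **not** emulate: the campaign's actual sampling
schedule and initial compositions (unpublished), sampling-volume
depletion, catalyst deactivation, temperature transients, or any
structured measurement error. Consequently, passing tests demonstrate the
correctness and self-consistency of the inference machinery under the
stated noise model — not agreement with the measured datasets. In
particular the total sum of squares of the synthetic campaign (≈ 18)
differs from the measured campaign's (≈ 4.8), since that value depends on
the real sampling schedule and composition spread.

## Problem sizes and determinism

Default fits use 20 multistart draws over 3 tests × 11–13 samples × 4
components (148 observations); the alternative-mechanism fits used for
discrimination checks use 6–8 draws, which is sufficient for the ranking
to stabilize. All randomness (noise, multistart) flows through explicit
integer seeds of `numpy.random.default_rng`; reports embed the seeds,
tolerances and Tmean used.

## Known limitations

- Rate-law families are fixed; no user-defined mechanisms.
- Uncertainties are linearized only (no bootstrap/Bayesian), and no
  AIC/BIC — discrimination uses R² plus parameter count by design.
- The ODE sensitivity is approximated by finite differences; forward
  sensitivity analysis is out of scope.
- Practical identifiability at two temperatures is poor in several
  directions; fitted parameter values should be read through their
  (often large) standard deviations.
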