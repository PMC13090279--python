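# Methods

## Model

The system couples a logistic prey ODE to a renewal (McKendrick-type)
transport equation for the predator age density.  The biology enters
through four channels: adult predators eat prey (`-b*y2` in the prey
equation, `k*x` in the predator birth rate), prey eat juvenile predators
(`+s*y1` for the prey, `g*x` juvenile death), predators starve when prey
are scarce (`mu_M * exp(-rho*x)`), and age takes its toll
(`mu_B(tau) = d_p * exp(d_ep*(tau - L))`, increasing with age).  Maturity
is a logistic switch at the maturation age `tau_star` with sharpness `nu`
(`nu = 100` is effectively a step; `nu = 1` a gradual transition spanning
a few time units).  The base adult birth rate `Btilde` has a *sharp*
cutoff at `tau_star` by construction, independent of `nu`; only the
prey-capture term `k*x` is gated smoothly.  Newborns enter at age zero at
rate `integral B(x, tau) u(t, tau) dtau`.

Two variants exist.  The baseline has unbounded birth terms and can blow
up in finite time in a small corner of parameter space (a positive
feedback between prey growth fed by juveniles and predator reproduction
fed by prey).  The saturated variant replaces `k*x` by
`k*x_hat*tanh(x/x_hat)` and `s*y1` by `s*y1_hat*tanh(y1/y1_hat)`
(defaults `x_hat = 20`, `y1_hat = 10`), bounding the prey by
`(r + s*y1_hat)/a` and removing blow-up entirely.

Default parameters (the reference set): `tau_star=1, g=0.2, nu=100,
r=0.4, a=0.01, k=0.3, b=0.8, s=0.2, zeta=10, mu_M=1, rho=5, d_p=0.4,
b_p=0.05, b_ep=0.1, d_ep=0.1`, lifespan cap `L=30` (density advected past
age 30 is discarded; equilibrium densities are ~1e-3 of their newborn
value there, so the cap is immaterial).  Sampling ranges for the
parameter studies are the per-parameter boxes in
`rolerev.PARAMETER_RANGES`.

## Discretization

Time and age share one step `h`, so each step shifts the density exactly
one age node (the scheme follows the characteristics): forward Euler for
the prey and for the decay along characteristics, trapezoid rule for the
birth integral and the population integrals, with half weight at the
maturation node in both the juvenile and adult integrals (the two weight
vectors sum exactly to the full-range trapezoid).  The printed scheme's
population integrals lag the density by one step; `advance_step` keeps
that lag by default and offers a synchronous variant, which the
fixed-point machinery uses (both have identical fixed points; trajectories
differ by O(h)).

The scheme is first-order.  The test suite verifies O(h) decay against a
closed-form renewal solution (prey pinned at carrying capacity so the
rates become fixed functions of age with logistic + exponential
antiderivatives) and O(h) self-convergence in the norm
`|x| + L1(u)`.

Positivity requires `h * mu < 1` on the grid.  Single-trajectory
integration treats a violation as an error (`NegativeDensityError`,
advising a smaller step).  The vectorized ensemble stepper instead floors
the offending survival factors at zero, flags the sample, and re-runs it
with the step halved (at most twice) — the per-sample version of choosing
the step by trial and error against negativity.  With the ensemble base
step 0.025, roughly 10% of Latin-hypercube samples trigger one
refinement.

Grids snap `tau_star` and `L` to the nearest node (strict mode errors
beyond 1e-6·h).  Blow-up is declared the first step any of `x, y1, y2`
exceeds the threshold (default 1000); checking every density node is
available but off by default, since the integrals dominate.

## Reduced models

Integrating the transport equation over the juvenile and adult age
segments and replacing the age-dependent base rates by density-weighted
averages at a coexistence equilibrium yields a three-variable ODE with
transition rate `D = u_eq(tau_star)/y1_eq`, adult birth rate `b2`, and
segment death rates `m1`, `m2`.  Setting `b2 = 0` and `mu_M = 0` recovers
the classical three-compartment role-reversal ODE, which the tests check
against an independent implementation.  The DDE reduction keeps the
maturation delay explicit: the maturing flux is the newborn flux one
delay ago, attenuated by the survival over the delay window with the
prey-dependent exponents integrated by the trapezoid rule between the two
endpoint times; the age-related burden is the closed-form integral
`M_B = integral_0^{tau*} mu_B`.  For `t < tau_star` the maturing
generation comes from the initial age density, decayed the same way over
`[0, t]`.  The DDE integrator is a fixed-step Heun scheme whose step
divides the delay exactly (no history interpolation error at the delayed
argument); the DDE history convention is constant-at-initial-values,
which the explicit initial-generation branch makes moot.  ODE integration
uses an adaptive Runge–Kutta method with a terminal blow-up event.

The ODE and DDE equilibria are close but provably distinct (the delay
survival factor replaces `D`); the tests assert both the proximity and
the non-identity.

## Equilibria, stability, limit cycles

Equilibria of the discrete scheme are zeros of `F(z) = z - Phi(z)` where
`Phi` is the one-step map on `(X, U)`; Newton's method uses a
forward-difference Jacobian with an absolute perturbation `1e-6` in the
prey column and relative perturbations `1e-6 * U[k]` in the density
columns (absolute fallback at zero nodes, which keeps the Jacobian
informative at the predator-free state).  Tolerance 1e-10 on the residual
max-norm, 50 iterations, no damping — warm starts make it unnecessary.

Warm starts come from two sources: a long integration (or the neighboring
cell's equilibrium during continuation), and a semi-analytic construction
from the renewal structure: at equilibrium the density is a survival
curve, and the prey level must make the predator's net reproduction
number `R0(x)` equal one.  `R0` is hump-shaped in `x`, and the scan runs
to ten times the prey-only carrying capacity because coexistence
equilibria with `x* > r/a` exist at small `g` — the prey there is
sustained above its own carrying capacity by feeding on juvenile
predators.

Stability is the spectral radius of the one-step map's Jacobian
(`dPhi = I - dF`); `(lambda - 1)/h` approximates the continuous-time
exponents.  A continuum cross-check (Laplace-transform characteristic
equation of the linearized system) agrees with the discrete exponents to
three digits at the reference cell.

Limit cycles are fixed points of the Poincaré first-return map on the
hyperplane `X = X*` through the unstable coexistence equilibrium (upward
crossings, linear interpolation between bracketing steps).
Levenberg–Marquardt minimizes `f(U) = 0.5*||U - G(U)||^2` (initial
damping 1e-3, adaptive ×10/÷10, stopping at `f < 1e-14` or gradient norm
1e-10), warm-started by plain map iteration, which already contracts when
the cycle is attracting.  Each Jacobian costs one map evaluation (one
period of integration) per density node, which is why cycle-finding is
done at coarse steps (h = 0.05 keeps it to seconds).

## Parameter studies

The Latin-hypercube design (scipy's stratified sampler; exactly one
sample per marginal bin, reproducible under a seed) covers the
15-parameter box.  Each sample integrates from the reference initial
state (prey 0.5; density 0.1 below the maturation age, 0.05 above, on
[0, 30]) to T = 500 with blow-up threshold 1000.  Classification:
early termination means blow-up; terminal predator population below 1e-6
means predator-free; otherwise the relative prey amplitude over
t in [400, 500] splits periodic (above 1e-3) from equilibrial.  The
1e-6 extinction cutoff is far below any attractor scale at the reference
parameters; the 1e-3 amplitude cutoff separates the clearly-flat from the
clearly-cycling tails.

The phase/bifurcation pipeline replaces the bulk amplitude rule with the
equilibrium machinery: integrate, test extinction on the *maximum* of the
predator population over the tail window (large-amplitude relaxation
cycles park the predator at astronomically low densities for long
stretches, so the terminal value alone declares false extinctions), then
Newton with warm-start continuation in decreasing `g`, then the map
spectrum: stable means equilibrial, unstable means periodic.

Fisher LDA uses the standard multiclass scatter matrices (between-class
`sum n_i (mu_i - mu)(mu_i - mu)^T`, pooled within-class), solved as a
generalized symmetric eigenproblem with ridge fallback; the two dominant
eigenvectors are orthonormalized by one Gram–Schmidt pass, and the
range-adjusted loadings `R @ W` (R diagonal with the per-parameter range
widths) make parameters with different units comparable.  scikit-learn's
LDA serves as an independent subspace cross-check in the tests, never as
the implementation.

## What the reduced-scale runs do and do not show

The ensemble tests run 300 samples at base step 0.025 (refined
per-sample as described) instead of 10,000 at 0.005; the binomial scatter
of a class fraction at n = 300 is about ±2.5 percentage points, so the
reduced runs bound the class fractions loosely but cannot resolve
percent-level differences.  The phase-diagram comparisons use 5×5 grids
at h = 0.05 rather than 39×101 at h = 0.0125; they capture which regimes
exist and the cell-wise ordering of instability between model types, not
precise boundary curves.

## Known limitations

* The coexistence equilibria of the baseline model at the reference
  parameters sit very close to marginal stability (continuous-time
  exponents of order ±1e-2) across wide swaths of the
  `(tau_star, g)` plane.  Classifications near the Hopf boundary are
  therefore delicate: a shift of a few times 1e-3 in the exponent moves
  the boundary substantially.  The package reports the spectral data
  (`spectral_radius`, leading exponents) alongside every label so users
  can judge marginal cells themselves.
* Weakly unstable cells produce relaxation cycles whose predator minima
  are astronomically small (1e-30 and below).  These are faithful to the
  deterministic equations but ecologically implausible; any demographic
  noise would cause extinction.  The classifiers treat recovery from such
  minima as coexistence (phase pipeline) or extinction (terminal-value
  ensemble rule); both conventions are stated where used.
* The forward-Euler/upwind scheme is first-order; coarse steps inflate
  oscillation amplitudes and, through the blow-up threshold, the blow-up
  rate.  The per-sample step-refinement policy mitigates, but quantitative
  ensemble statistics should use the fine step (0.005) when runtime
  allows.
* No adaptive time stepping, no higher-order schemes, no Floquet analysis
  of the infinite-dimensional cycles, and no continuation beyond simple
  warm-start marching.
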