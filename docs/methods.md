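# Methods

## The model

`demecycles` simulates competing microbial strains in a spatio-temporally
structured habitat: a large collection of separated compartments (demes —
tidal pools, droplets) that are periodically pooled, diluted and reseeded
with fresh medium. One cycle has two phases.

**Growth phase.** A deme seeded with integer counts `n = (n_1, n_2, ...)`
and resource `S(0) = S0` evolves by

    dN_i/dt = alpha_i(t) N_i,
    dS/dt   = -sum_i alpha_i(t) N_i / phi_i(t),

with per-strain growth rate `alpha_i(t) = alpha (1 + dalpha_i) A(t)` and
yield `phi_i(t) = phi (1 + dphi_i) Y(t)`. The trait deviations `dalpha_i`,
`dphi_i` are small constants relative to the strain averages; `A(t)` and
`Y(t)` couple all strains identically to the shared environment. Growth
stops when the resource is exhausted (`alpha_i = 0` for `t > T_depl`).
Everything is non-dimensionalized (`alpha = phi = 1`): time is `alpha*t`,
resource is measured in cell equivalents `S*phi`, so a deme grows roughly
`log(S0*phi / n)` e-folds before depletion.

Three interaction models:

* **base** — `A = Y = 1`: pure consumer-resource competition.
* **antibiotics** — `A(t)` is a Hill function of the antibiotic
  concentration `b = B/mu` (MIC units), `A = (1 - b^kappa)/(1 + b^kappa/gamma)`:
  growth at `b = 0`, zero net growth at the MIC `b = 1`, death saturating at
  `-gamma` for large `b`. Producer strains degrade the antibiotic,
  `db/dt = -sum_i rho_i N_i b`; `b(0) = b0` is replenished every cycle.
  The within-deme outcome is a race: either the producers push `b` below 1
  before the population dies out, after which the deme recovers and depletes
  its resource, or the antibiotic wins and the deme dies.
* **pyoverdine** — the siderophore raises the effective yield,
  `Y(P) = sigma - (sigma - 1) exp(-P)`, with `dP/dt = sum_i rho_i N_i` and
  `P(0) = 0` each cycle (fresh medium; no carry-over).

**Mixing phase.** All demes are pooled, diluted by `d`, and reseeded. With
many demes, seeding is Poisson per strain, and the dynamics over cycles
closes on the vector of mean inoculum sizes:

    nbar[tau+1] = d * E[ N(T_mix; n) ],  n ~ Poisson(nbar[tau]) per strain.

The change of the mean composition per cycle obeys a Price equation:
`Delta xbar = <Delta X> + Cov[X, N/<N>]` — within-deme selection (local
competition, usually favoring the faster grower) plus between-deme selection
(demes that end larger are over-represented in the pool). Simpson's paradox
is the regime where the first term is negative and the covariance term
overcompensates.

## Numerical implementation

**Expectation over seeding.** The Poisson expectation is an exact sum over a
truncated integer lattice. Per-strain support is `[0, K]` with `K` the
smaller of `ceil(m + 10 sqrt(m+1) + 10)` and the upper quantile leaving at
most `mass_tolerance / n_strains` (default total `1e-9`) in the tail.
Probabilities are used unnormalized and the neglected joint mass is
reported; refining the tolerance moves results by less than the prior
neglected-mass bound.

**Price identity.** All three terms are computed over the same truncated
ensemble, with empty demes assigned the pool composition and zero change
(so `<x> = xbar` holds exactly for the untruncated sum). This makes the
decomposition identity exact to machine precision for every interaction and
state; the decomposition's `delta_xbar` differs from the full map's change
only by the neglected Poisson mass.

**Deme growth, fast path.** `grow_deme` integrates the full system with a
stiff-capable SciPy solver (default LSODA, rtol 1e-8, atol 1e-10) and event
detection for depletion (tolerance `1e-9 * S0phi`); it is the reference
implementation and supplies trajectories. Lattice sums need 1e4–1e5 deme
solutions per world, so they use reduced forms of the same equations:

* base: the exact solution — `N_i = n_i exp((1+dalpha_i) t)` with `T_depl`
  from a safeguarded Newton root of the substrate balance;
* antibiotics: since all strains share `A(t)`, with `G = int A dt` the sizes
  are `N_i = n_i exp((1+dalpha_i) G)`, leaving a 3-state ODE in
  `(G, log b, s)` (log-antibiotic removes the stiffness of enzymatic decay);
* pyoverdine: growth rates are constant, so `N_i(t)` and `P(t)` are closed
  forms and only `s(t)` is integrated.

The reduced systems are integrated with an adaptive Dormand–Prince 5(4)
stepper (rtol 1e-10) compiled with numba, with the depletion time located by
bisecting the final step. Tests hold the fast path to within 1e-6 relative
of `grow_deme`. Results are memoized per world in a dense table indexed by
the integer inoculum.

**Sign conventions and cutoffs.** When the antibiotic makes the effective
growth rate negative, the literal consumption equation would return
substrate as cells die; the default clamps consumption to zero during death
(`literal_consumption=True` restores the literal reading — the two differ
only in deep death phases). Populations are continuous; no extinction
cutoff is applied by default (an optional end-of-growth cutoff exists for
sensitivity analysis). One observable consequence: an all-producer
antibiotic population is invadable by a rare non-producer in the default
model (its boundary fixed point is a saddle), because an infinitesimal
surviving fraction regrows deterministically; with a cutoff the non-producer
would be lost in the death phase instead.

**Phase plane.** Isoclines are found by bisection/Brent root-finding of
`Delta nbar` (or `Delta xbar_1`) along log-spaced brackets sized from the
interaction's own scales; multiple roots per grid point are reported as
separate branches. Fixed points come from damped Newton iterations on mean
counts (multi-start), boundary points from the restricted single-strain
maps, and the extinction state is always examined. Stability is classified
from the finite-difference Jacobian of the one-cycle map (central step
1e-4 relative, Richardson-checked) via the discrete-map criterion
`|lambda| < 1`, with a marginal band of 1e-6. Limit cycles are detected by
iterating up to 5000 cycles and requiring a bounded, non-convergent orbit
whose radius per angular section around its centroid agrees between the
early and late thirds of the tail to 1%.

**Outcome classification.** Total size equilibrates within a few cycles
while composition moves slowly (time-scale separation). When a trajectory
has not converged within the horizon, the classifier reduces the dynamics
to the slow manifold: it root-finds the attracting quasi-equilibrium
`nbar_eq(x1)` and follows the sign of `Delta xbar_1` along it to the next
root or boundary, then verifies any candidate attractor by its eigenvalues.
Coexistence requires a stable interior attractor with `x1` at least 1e-3
from the boundaries.

## Study conditions

The standard environment is `S0*phi = 1e5`, `alpha*T_mix = 24` (ample time
for depletion: `log(1e5) ~ 11.5`). Headline configurations:

* Dilution line: `d = 6e-4` (`d*S0phi = 60`); the single-strain equilibrium
  solves `nbar = d(nbar + S0phi(1 - e^-nbar))`, i.e. ~60.04.
* Antibiotics: `b0 = 1.25`, `kappa = gamma = 2`, `rho_1/alpha = 5e-3`,
  producer cost `dalpha_1 < 0`. A single producer cell cannot win the
  degradation race; ~14 cells can. The stability sweep holds `d*S0phi = 60`
  and lowers the cost from 1e-1 to 1e-3: the interior fixed point turns
  from unstable (intersection on the antibiotics-limited, ~1/x1 branch of
  the size isocline) to stable (intersection on the dilution line), with a
  complex eigenvalue pair crossing the unit circle near cost ~9e-3 and a
  stable invariant loop (both `nbar` and `x1` oscillating) just outside it.
* Pyoverdine: `sigma = 2`, `rho_1/alpha = 1e-3`; an all-producer population
  equilibrates at twice the non-producer level, and a costly producer
  (`dalpha_1 = -1e-3`) coexists stably at a small interior fraction.
* Trade-off coexistence scan: axes `dalpha_1` in log-spaced `[-0.4, -1e-3]`
  and `dphi_1` in `[0, 0.5]` (strain 2 neutral), `d = 1.075e-5`
  (`d*S0phi = 1.075`). Coexistence under a pure growth/yield trade-off
  requires a strong bottleneck (mean inocula of order one cell) so that
  demes seeded with the efficient strain alone are common; the chosen
  dilution places the large-trade-off coexistence strip fully inside the
  grid with band edges independent of `dalpha_1` across a two-fold range,
  while the small-trade-off band collapses below the grid resolution.

Where a figure-style parameter is needed that the captions do not fix
(notably `d` for the stability sweep and the scan), the values above are the
package's own choices, selected to realize the described regimes.

## What the generator does and does not emulate

Synthetic experiments cover Poisson seeding, deterministic within-deme
growth, and perfect global mixing. Real systems add demographic noise
during growth, non-Poisson seeding, imperfect mixing and deme-size
heterogeneity, cell death on long time-scales, and spatial structure within
demes — none are modeled, so passing tests support the mean-field,
deterministic-growth picture only. The finite-deme Monte Carlo exposes
finite-M fluctuations (drift in composition and absorbing extinction) but
still grows each deme deterministically.

## Numerical choices and limitations

* Tolerances: integrators 1e-8/1e-10 (reference) and 1e-10 (fast path);
  isocline roots 1e-6 relative; Newton residual 1e-10 relative; fixed-point
  dedup 1e-4 relative; truncation mass 1e-9.
* Degenerate inputs: empty inocula return empty results; an empty mean
  state has undefined composition (rejected where composition is required);
  identical strains report a degenerate (everywhere-stationary) composition
  isocline and a `neutral` outcome.
* The composition-isocline level of the base trade-off follows the
  `|dphi_1/dalpha_1|` scaling but sits a factor ~3–4 above the leading-order
  closed form; the closed forms are approximations for overlay, with "~"
  relations carrying explicit calibratable prefactors (default 1).
* Scan cells at very small costs rely on the slow-manifold reduction;
  near-degenerate cells (selection below ~1e-12 per cycle) are reported as
  undetermined rather than forced into a label.
* Lattice size is capped (4e6 points); states far outside the dynamically
  relevant range raise a resource error instead of silently coarsening.
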