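# Methods

## The model

Two transcription factors X and Y each activate their own gene and repress
the other's.  The package implements this circuit at two levels.

**Elementary chemistry.**  Each gene's promoter is a four-state molecule:
free (`x`), activator-bound (`xX`), repressor-bound (`xY`), and doubly bound
(`xXY`).  Binding is mass-action with equilibrium constants `K_x` (activator
to own promoter), `K_yx` (repressor to free promoter) and `K_xxy` (repressor
to the activator-occupied promoter); protein is produced at rate `alpha_x`
only from the activator-bound, repressor-free complex and degrades first
order at `delta_x`.  Two chemistries are distinguished by the repressor's
affinity for the occupied promoter:

* *Model 1 (independent binding)*: `K_xxy = K_yx` — the repressor does not
  see the activator.  The promoter partition function then factorizes as
  `(1 + K_x[X])(1 + K_yx[Y])`.
* *Model 2 (ternary complex)*: `K_xxy` free.  Partition function
  `1 + K_x[X] + K_yx[Y] + K_x·K_xxy[X][Y]`; the repressor-bound promoter is
  a dead end for the activator (no `xY + X` channel), so the doubly-bound
  state is reached only via `xX + Y`.

Model 1's published reaction list is written with an *effective* activation
propensity (itself a reduced quantity); the elementary realization used here
is the independent-binding four-state promoter, whose rapid-equilibrium
partition function is exactly the product form — this is also why Model 1 is
implemented as the `K_xxy = K_yx` slice of the Model 2 network topology.

**Reduced system.**  Assuming binding/release equilibrate fast relative to
production and degradation, and eliminating the promoter states through the
partition function, both chemistries give

    d[X]/dt = a[X] / Z_x([X],[Y]) − d[X],   a = alpha_x·x_tot·K_x,

with `Z_x` the partition function above.  When `Z` factorizes this is the
generic planar system

    dx/dt = a·x/((1+b·x)(1+c·y)) − d·x,   b = K_x, c = K_yx, d = delta_x,

(mirrored for y with production scale `f`).  The `[X][Y]` cross term present
in `Z` either way is an effective promoter-bound heterodimer that emerges
from independent monomer action — no protein–protein cooperativity is
assumed in either chemistry.  Factorization is tested at 1e-12 relative
tolerance on `K_xxy` vs `K_yx`; near-misses are reported, never silently
factorized.

## Steady states and stability

For symmetric production (a = f) the four isolated steady states are known in
closed form: the origin; the committed states `((a−d)/(b·d), 0)` and mirror,
whose positions do not depend on `c`; and the interior diagonal state `(s,s)`
with `(1+b·s)(1+c·s) = a/d`.  All closed forms are polished by a Newton-type
root finder (hybr, tol 1e-12) before classification — protection against any
transcription slip in the printed forms — and a fixed point is accepted only
if the right-hand-side residual is ≤ 1e-8.  For a ≠ f the diagonal ansatz
fails and the interior branch is located by multi-start root finding on a
5×5 grid over the positivity box, deduplicated at 1e-8 in the max norm;
coordinates in (−1e-8, 0) are snapped to 0, as concentrations.

Stability comes from the analytic Jacobian.  The classification zero
tolerance is scale-aware, `1e-9·max(|λ|, |μ|, d)`, which is what lets the
exactly-zero eigenvalue on the degenerate manifold be recognized as such
rather than as a tiny stable/unstable direction.

Positivity of the nontrivial states requires `a > d` and `f > d`; a violation
is reported per lost branch (`lost_states`), not raised, so parameter sweeps
can continue through bad regions.

## Bifurcation in q = c/b

`q` is swept by varying `c` at fixed `b` — this keeps the committed branches
literally constant along the diagram.  At the interior diagonal state the
eigenvector transverse to the diagonal is `(1, −1)` with eigenvalue

    e_perp = d·s·(c − b) / ((1+b·s)(1+c·s)),

which changes sign exactly at `c = b`.  `critical_q` bisects this sign over
a user bracket (default [0.1, 10]) to a bracket width of 1e-6; the returned
midpoint equals 1 for every admissible symmetric parameter set, as the sign
structure of `e_perp` dictates.  The default sweep grid is 101 log-spaced
points in [0.2, 5]; the critical point is always refined by bisection, never
read off the grid.  Branch identity between adjacent grid points is enforced
by nearest-neighbor matching, with the interior branch and its degenerate
q = 1 point treated as one family.

## The degenerate manifold (b = c)

At `b = c`, `a = f` the interior steady-state equations collapse to
`(1+b·x)(1+b·y) = a/d`, a curve joining the two committed states across the
interior.  The package parameterizes it by `x` on `[0, x_max]`,
`x_max = (a−d)/(b·d)`, with `y(x) = ((a/d)/(1+b·x) − 1)/b`.  On the manifold
the Jacobian is rank-deficient: its determinant vanishes identically, giving
eigenvalues `μ = 0` and

    λ(x) = trace = −d·b·( x/(1+b·x) + y/(1+b·y) ) < 0,

so the manifold attracts transversally and is indifferent longitudinally.
`μ` is reported as exactly 0 (the raw eigensolver value is kept in
`mu_raw` for diagnostics).  `λ` has its interior minimum at the diagonal
point `x* = (√(a/d)−1)/b`; `lambda_min` locates it by bounded scalar
minimization and snaps to the closed-form diagonal point when consistent.
Two presets ship for the eigenvalue profile: the reference set
(b = 0.5, manifold on [0, 2]) and a unit-interval variant (b = 1, manifold
on [0, 1]).

## Stochastic simulation

Euler–Maruyama with additive, independent Gaussian noise per coordinate:
`state += rhs·dt + σ·√dt·ξ`, then each coordinate clamped at zero from below
(projection — chosen over reflection or rejection as the simplest scheme
that leaves the update untouched elsewhere and never produces negative
concentrations).  With σ = 0 the integrator is bitwise identical to plain
Euler.  Defaults: dt = 0.01, 1e6 steps (T = 1e4), σ = 0.05, burn-in 10%,
100×100 bins, mode threshold 0.1 of the peak, mode merge radius 0.5.  All
randomness flows from one explicitly seeded generator, and the seed is
embedded in every output.

**Ensemble landscapes.**  At σ = 0.05 the committed basins are separated by
an effective barrier tens of noise standard deviations wide; a single
trajectory never crosses between them on any feasible timescale (the
escape probability per step is of order e^−100).  The stationary landscape
of a multistable regime is therefore estimated the way one observes a cell
population: `attractor_landscape` splits the configured step budget across
an ensemble of trajectories (default 10) started uniformly over the
positivity box and pools their post-burn-in samples.  Mode counts of the
pooled density are stable across seeds in the monostable (1 mode) and
bistable (2 modes) regimes.  The detected mode of a committed attractor sits
slightly inside the fixed point (at the reference parameters, near
x ≈ 1.8 rather than 2.0): the zero-clamp folds the repressed coordinate's
fluctuations upward, which through the cross-repression term shifts the
dominant coordinate's density peak — a property of the noisy system, not an
estimation artifact.  In the degenerate regime the density forms a flat
ridge along the manifold; a ridge has no robust mode count (small-sample
bumps along it come and go with the seed), so the degenerate diagnostics are
the manifold-residence fraction (distance to the manifold via its discretized
x-parameterization, 4001 points), the negative x–y correlation of the
samples, and the proximity of the time average to the λ-minimum point.

**Full-network oracle.**  The mass-action network is integrated with LSODA
at rtol 1e-9 / atol 1e-12; promoter totals are conserved along trajectories
to 1e-9 relative.  Binding/release pairs are realized as
`(rate_scale·K, rate_scale)`, so every equilibrium constant is exact and one
number controls timescale separation.  Note that the *fixed points* of the
full network coincide with the reduced model's at any `rate_scale`: at a
steady state every binding flux vanishes individually, which is the
equilibrium condition itself.  The content of the rapid-equilibrium
assumption is dynamical, and is verified as such: at fixed finite time the
discrepancy between the full network's free proteins and the reduced
trajectory shrinks monotonically as `rate_scale` runs through {1, 1e2, 1e3}.

## Problem sizes and numerical choices

The shipped analyses are desk-scale by construction: steady-state and
bifurcation work is closed-form plus root polishing (milliseconds), the
degenerate manifold is sampled at 200 points, stochastic landscape runs use
1e6 Euler–Maruyama steps per regime and seed, and the stiff full-network
integrations run to t ≈ 500 at rate scales up to 1e3.  Dedup tolerance 1e-8,
residual acceptance 1e-8, factorization tolerance 1e-12 relative, bisection
bracket width 1e-6 (interfaces expose all of these).

## What the defaults do and do not show

All quantities are dimensionless; the reference parameter set a = f = 1,
d = b = 0.5 with q varied through c is the study condition throughout.  The
stochastic runs emulate intrinsic expression noise as additive and
state-independent — real single-cell noise is state-dependent (roughly
Poisson-like in copy number) and extrinsic components are correlated between
genes, so passing landscape tests here demonstrates the geometry of the
deterministic backbone under generic perturbation, not a quantitative noise
model of any particular cell system.  The chemistry omits mRNA, chromatin
and multi-step activation deliberately: the point of the model pair is that
the fate-decision geometry survives coarse-graining and does not require
molecular cooperativity.  No continuation software is used (the 2-D system
is fully tractable by sweep + bisection), and no quasi-potential is
computed — the stationary density is the only "depth" proxy.
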