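# Methods

## Model

Each cell carries four non-negative, dimensionless expression levels
`(A, X, Y, Z)` scaled so that steady states lie between 0 and 1.  `A` is
an upstream inducer expressed in early progenitors; `X` a transiently
expressed pro-endocrine factor; `Y` the exocrine (acinar) determinant;
`Z` a self-activating terminal islet marker.  The deterministic drift per
cell is

    dA/dt = 1/(1 + r Y^n + r Z^n) − A
    dX/dt = q A^n/(q + a X̄^n) − X
    dY/dt = (q A^n + b (Y·Ȳ)^n)/(q + b (Y·Ȳ)^n + c X^n + c Z^n) − Y
    dZ/dt = (X^n + s Z^n)/(1 + s Z^n) − Z

with additive Gaussian white noise of amplitude `eta_x`, `eta_y` on the X
and Y equations.  Two contact-mediated couplings act through the
neighbour averages `X̄`, `Ȳ`:

* **lateral inhibition** (`a X̄^n` in the X denominator): neighbouring X
  suppresses a cell's own X production regardless of its own state —
  the classic Delta/Notch competition that produces alternating fates;
* **lateral stabilization** (`b (Y·Ȳ)^n`): the multiplicative form means
  the positive feedback engages only when Y is expressed on *both* sides
  of a contact, so non-expressing neighbours contribute nothing.  The
  molecular carrier (homotypic adhesion or junctional signaling) is
  deliberately left abstract.

Default parameters, used everywhere unless stated: `a = 1000`,
`b = 2000`, `c = 500`, `q = 1e-4` (weak induction), `r = 100`, `s = 50`,
`n = 3` (step-like Hill response), `eta_x = eta_y = 1e-3`.  Initial
conditions come as two presets: *embryo* `(A, X, Y, Z) = (1, 0, 0, 0)`
(progenitors expressing only the inducer) and *adult* `(0, 0, 1, 0)`
(differentiated acinar tissue).

Fate classification: a cell is *islet* when `Z > 0.5`, *acinar* when
`Y > 0.5` with `Z ≤ 0.5`, *progenitor* otherwise.  Steady states cluster
near 0 and 1, so any mid-range threshold yields identical labels; 0.5 is
the symmetric choice and both thresholds are configurable.  A
hypothetical state with both markers high is classed islet; under the
reference parameters the fates are mutually exclusive and that case is at
most transient.

## Tissues and neighbour signals

Topologies: a `width x height` hexagonal lattice in odd-r offset
coordinates (odd rows shifted right) with Bernoulli site occupancy;
the 3-cell mutually adjacent minimal tissue (the smallest system that can
hold a mixed fate pattern); and arbitrary symmetric graphs from edge
lists.  Lattice boundaries are periodic by default (this removes edge
artefacts from pattern statistics; an even row count is required for a
consistent periodic hex wrap) and can be set to fixed/void.

Neighbour signals divide the *sum* of neighbour expression by the
topology's nominal coordination number (6 on the hex lattice, 2 on the
triangle): empty sites contribute zero but still count in the
denominator.  This normalization makes the received signal scale with
local cell density, which is the mechanism behind the density dependence
of conversion — a cell pair is genuinely less stabilized than a cell in
bulk tissue.  Averaging over occupied neighbours only would erase that
distinction.  An isolated cell receives `(0, 0)`.

## Stochastic integration

The coupled SDE system is advanced by the second-order Heun–Maruyama
scheme at fixed `dt = 0.02`:

    predictor  s* = s + f(s) dt + g dW
    corrector  s' = s + (f(s) + f(s*)) dt/2 + g dW

with the *same* Wiener increment `dW = sqrt(dt) N(0,1)` in both stages
(fresh draws would break the convergence order) and neighbour signals
recomputed from the predictor for the corrector drift.  Noise is additive
and only on X and Y (`g dW = (0, eta_x dW_x, eta_y dW_y, 0)`), so the Itô
and Stratonovich readings coincide.  One seeded generator drives a run;
draws are made in a fixed `(n_cells, 2)` block per step, so trajectories
are bit-reproducible.

States are clamped at zero after every update.  Because the odd Hill
exponent makes negative arguments meaningless, the clamp is part of the
scheme's contract.  Components resting at the zero boundary (X and Y in
quiescent cells) are clamped on roughly half of their noise kicks — that
is a structural consequence of additive noise at an absorbing boundary,
not a numerical pathology — but the clamp only ever removes excursions of
order one noise increment (`eta sqrt(dt) ≈ 1.4e-4`, measured worst case
`5.6e-4`), three orders of magnitude below the expression scale.  The
test suite asserts the magnitude bound.  No upper clamp is applied; box
invariance of the drift keeps the deterministic flow inside `[0, 1]`.

Scenario schedules (parameter switches such as `b -> 0` at `t = 0`) are
applied at the first step boundary at or after the scheduled time; a
pre-equilibration burn-in (default 20 time units for conversion
protocols) integrates with pre-switch parameters at negative times so the
switch marks `t = 0`.

## Steady states, stability and folds

Fixed points of the deterministic coupled system (dimension
`4 x n_cells`) are found by Newton iteration with a closed-form Jacobian,
including the inter-cell blocks through `X̄` and `Ȳ`; residual tolerance
`1e-10` in max norm, at most 100 iterations, failures returned as
explicit non-converged results (the fold bisection relies on that).
Stability is read from the spectrum of the converged Jacobian with a
`1e-8` real-part tolerance — permutation symmetry of the triangle forces
eigenvalue multiplicity, so stability calls never depend on eigenvalue
ordering.

*Directional* stability ("stable with respect to perturbations in Y,
unstable in X") assigns each eigenvalue to the variable with the largest
absolute **left**-eigenvector loading summed over cells: the left
eigenvector is the functional that measures how strongly a perturbation
excites the mode, which is exactly the "does a kick in this variable
depart" notion.  (The right eigenvector describes which variables *move*
once the mode grows — at the progenitor saddle that is dominated by Y
even though only X perturbations excite it.)  An integration probe
(single-cell kick of `1e-3`, 20 time units, departure beyond ten times
the kick) is available as an independent fallback for ill-conditioned
eigenbases; for saddles with a tiny but nonzero projection on a variable
it is conservative by construction.

Branches are traced by natural-parameter continuation with geometric
steps (the couplings span decades) and adaptive step halving on Newton
failure; a solution is branch-continuous if Newton converges, stays
non-negative, and moves less than 0.3 in max norm.  Folds are refined by
bisection on existence of the branch-continuous solution, seeded from the
nearest accepted point, to a prescribed width (`1e-4` in `b`, `1e-5` in
`a`).

### The two critical couplings

With all other parameters at their defaults:

* The **homogeneous all-acinar** state of any fully coordinated tissue
  obeys the scalar balance `q Y = b Y^(2n) (1 − Y)` (corrections from A,
  X, Z enter below `1e-9`), whose fold has the closed form
  `b = q · 6^6/5^5 = 1.4930e-3` at `Y = 5/6`.  The package's coupled
  12-dimensional continuation reproduces this value, and the test suite
  checks it against the closed form.
* An acinar cell stabilized by a **single** acinar neighbour sees
  `Ȳ = Y/2`, which rescales the fold by `2^n = 8` to `1.1944e-2`.  On
  the 3-cell tissue this is the fold of the mixed configuration (two
  acinar + one islet cell), and it is the *operative* critical
  stabilization `b_c ≈ 0.012`: below it the acinar fate can no longer be
  maintained anywhere but in a fully intact neighbourhood, and any
  configurational defect unravels the tissue cell by cell.  The package
  reports this single-neighbour fold as `b_c` (`critical_stabilization`,
  default `branch="mixed"`) and exposes the homogeneous fold as
  `branch="acinar"`.
* The **progenitor** branch at `b = 0` (high A, low promiscuous X and Y)
  vanishes at `a_c = 1.68e-3` in a saddle-node with a partner branch of
  higher Z: as inhibition weakens, X rises as `(q/a)^(1/4)` until the
  self-activating Z switch fires.  Below `a_c` there is no multipotent
  intermediate and conversion is a direct lineage switch.

Both folds are recomputed from scratch by `scripts/acceptance.py`.

## Protocols and their statistics

* **development** — embryo preset, full lattice, noise on, `t_end = 100`.
  Noise breaks the symmetric "promiscuous" co-expression of X and Y;
  lateral inhibition amplifies the differences, committed acinar cells
  recruit neighbours through the stabilizing feedback (fate-wave
  propagation), and the tissue resolves into scattered islet cells inside
  acinar fields.  Without noise the symmetric state never resolves.
* **conversion** — adult preset, burn-in 20, then `b = 0`
  (`conversion_stab`), `a = b = 0` (`conversion_both`) or `a = 0` only
  (`inhibition_only`); `t_end = 200`.  Conversion fraction uses the cells
  occupying the lattice at `t = 0` as denominator; `time_to_half` is the
  first recorded time the islet fraction of a replicate exceeds 0.5.
* **recovery** — `b = 0` at `t = 0`, restored at `t_rec`.  Outcomes are
  classified from the final fate map: *completed* (islet fraction
  ≥ 0.99), *arrested* (≤ 0.01, the tissue returned to acinar), *mixed
  re-decision* otherwise.  The thresholds are package-defined.
* **density / shape sweeps** — adult preset with `b` held fixed
  (conversion driven by missing neighbours, not by a schedule),
  `t_end = 300`, default 20 replicates per condition with mean and
  standard error reported.  Shape sweeps take explicit occupancy masks
  and report conversion against mean occupied neighbours per cell
  (aggregate compactness).

Scenario clocks are in the model's dimensionless time; the `t_end`
defaults (100 / 200 / 300) are chosen so each protocol reaches a steady
fate classification at the reference parameters, and all are
configurable.  The default sweep lattice is 30×30 — large enough for
pattern statistics, small enough for replicate sweeps on a laptop; the
unit-test suite uses 8×8 to 12×12 tissues for speed and the acceptance
tests run the full 30×30 conditions.

Replicates of one scenario are advanced as a single block-diagonal system
(a disjoint union of the replicate tissues), which keeps the vectorized
step cost low.  Per-replicate occupancy masks are drawn from seeds
spawned deterministically from the scenario seed; one noise stream per
scenario drives all replicates.  Equal specifications therefore give
bit-identical results, and two scenarios sharing a seed and tissue layout
(e.g. the paired comparison of `conversion_stab` vs `conversion_both`)
see identical noise realizations.

## What the simulated tissue does and does not emulate

Occupancy is independent Bernoulli per site: aggregates are random
clusters, not the connected acini of enzymatically dissociated tissue
(explicit masks cover prescribed shapes).  Cells do not move, divide, die
or re-aggregate; the lattice is static.  The stabilization pathway is a
single abstract term, so agreement of simulations with the model's own
bifurcation analysis says nothing about which molecular carrier
implements it in real tissue.  Passing tests demonstrate the internal
consistency and the qualitative mechanisms (multistability, sequential
vs direct conversion, density dependence) — not quantitative rates in
biological time units, which the dimensionless model does not provide.

## Numerical choices and limitations

* Newton tolerance `1e-10`, eigenvalue tolerance `1e-8`, continuation
  jump bound 0.3, fold bisection widths `1e-4` (b) / `1e-5` (a) — solver
  choices, not model statements.
* `dt = 0.02` is fixed; there is no adaptive SDE stepping, no
  higher-order or implicit scheme.  The noise-free stepper agrees with an
  adaptive ODE reference to `1e-4` on the 3-cell protocols, and the
  stepper reproduces the Ornstein–Uhlenbeck stationary variance
  `eta^2/2` at this `dt` within Monte-Carlo error.
* Continuation is single-parameter and restricted to small systems
  (the bifurcation module is meant for the 3-cell tissue and small
  graphs, not lattices); there is no two-parameter surface or Hopf
  detection.  Projections onto `sum(Y)` can make branches appear to
  intersect; full state vectors are kept on every branch point.
* CSV output uses `%.17g` formatting so values survive the text round
  trip exactly; re-reading with pandas requires
  `float_precision="round_trip"` for bit equality.
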