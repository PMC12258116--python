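# Methods

## Discrete model

The simulator is an agent-based model on a synchronous clock: one step
is one cell cycle. A cell's behaviour is fully determined by three
immutable properties — maturation period `c`, whole-maturation age
`n_wm`, lifespan `L` (all in cycles) — plus its mutable age, generation
and split angle. State follows age: immature (I) for `age < c`, mature
and dividing (M) for `c ≤ age < n_wm`, wholly mature and sterile (W)
for `n_wm ≤ age < L`, dead at `L`. The clonogenic cell (label 0,
generation 0, the stem-cell analogue) is permanently mature and
immortal and anchors the structure.

Division is asymmetric production: a dividing cell persists and appends
one immature daughter. Division eligibility is evaluated on the
advanced clock, so a cell born at time `b` first divides at `b + c` —
this is what makes the division-order table come out with cell 1 (born
t = 1) first dividing at t = 7 for c = 6. Within a step, parents divide
in ascending label order (clonogenic first) and children take
consecutive labels continuing the global count, so labels are the
division order. Dead cells are dropped from counts but kept in the
lineage record; labels are never reused.

### Non-spatial (linear) model

With `n_wm = L = ∞` the mature cells at time t are exactly the cells
born by `t − c`, giving the identities `M(t) = N(t−c)`,
`I(t) = N(t) − N(t−c)` and the recurrence `N(t) = N(t−1) + N(t−c)`
with `N(t) = t + 1` for `t ≤ c`. The tests verify the simulated
population against this recurrence as an independent oracle, and the
recurrence layer (`sequences`) is kept in exact integer arithmetic
because N(t) overflows 64-bit integers well before t = 300 for small c.
The simulator's seeding `N(t) = t + 1` corresponds to the flat
Fibonacci p-number seeding `F_0 … F_{c−1} = 1` through the index shift
`N(t) = F_{t+c−1}`.

The lineage exports to Newick with one node per cell, children = direct
progeny in birth order, and the cell's birth time as its branch
annotation; a single division is `(1:1)0;`. Leaves are therefore the
cells that have not divided within the horizon.

### Spatial (rosette) model

Cells occupy a planar lattice generated by unit steps along the
`D = 360/R` discrete directions (hexagonal for R = 60°); the default
`R = 360/c` ties the division geometry to the maturation period.
Positions are exact unit-vector sums stored as floats and keyed at
6-decimal precision — orders of magnitude below the lattice spacing at
every size the package simulates (the scheme is not meant for D with
a dense generated subgroup, e.g. D = 5 or 7, at very large radii).

Each division places the daughter one step along the parent's current
split angle; both daughters then rotate their orientation by one
increment. Rotation is applied per division (not per waiting cycle);
for mature cells, which divide every cycle, the two conventions
coincide, and we adopt the per-division form uniformly so an immature
cell divides for the first time along the orientation it inherited at
birth. If the target is occupied, the whole occupied chain along the
division ray is pushed one position outward before placement — chains
preserve radial order, displaced cells keep their own split angle, and
the origin is skipped (the clonogenic cell is immovable; chains pass
over it — this does get exercised in grown structures). Deaths vacate
positions without back-filling; vacancies may be re-occupied later.
Since placement never creates or destroys cells, all population counts
coincide exactly with the linear model under equal parameters.

**Symmetry.** Because the clonogenic cell seeds one branch per cycle,
the D branches are developmentally staggered by one cycle each, and the
grown structure cannot be exactly D-fold symmetric at a fixed time (the
non-origin count `N(t) − 1` is generally not divisible by D, and branch
populations differ by roughly a factor ρ between neighbours). What the
model does have, and what the tests assert, is: exact D-fold symmetry
of the completed leaflet ring at `t = c` (positions and states), and
near-complete positional overlap (> 60 %, rising with t) of the grown
structure under a 360/D rotation, versus zero overlap under a
half-increment control rotation. `symmetry_order` itself reports the
exact multiset symmetry and is kept strict.

### Steady state

The steady-state schedule lowers the whole-maturation age linearly with
generation, `n_wm = max(n_wm0 − g, c)`: later generations perform fewer
of the `n_wm − c` divisions, and generations with `n_wm = c` perform
none. Together with a finite lifespan this bounds the population. The
reference configuration (c = 6, n_wm0 = 11, L = 35) settles to an
exactly constant population (2276 cells) after roughly 3L cycles, with
mature cells confined near the origin and wholly mature cells streaming
outward to die near the edge; the tests assert exact constancy and a
zero linear trend over cycles 105–210. Lifespan controls the overall
radial extent (extent grows substantially with L, though not
proportionally) while leaving the dividing-region radius essentially
unchanged — the qualitative claim the model supports.

The cylinder projection maps `(x, y)` to angle `2π(x mod W)/W` and
height `y` with default circumference W = 42 cells, the crypt-like 3D
view. It is injective whenever the planar width is below W — true for
the early cell-level structure (t ≈ 27), not for the fully grown
steady structure, whose width (~70) exceeds the default circumference.

### Branch counting

`branch_counts` assigns every cell beyond the unit-radius leaflet ring
to the angular sector centred on its nearest branch ray (ties toward
the lower ray index); counts therefore sum to `N(t) − 1 − D` once the
ring is complete. The per-branch series is validated against the
simulation itself: totals grow at the golden p-section rate ρ (checked
at t = 24 within 2 %). No closed-form generating coefficients are
asserted.

## Continuous model

The four-compartment linear system (state order M, I, W₁, W₂) models
division as production without self-loss — M yields an extra I at rate
k₁, I an extra M at rate k₂ — and differentiation as transfer out of
the proliferative pool (I→W₁ at k₃, M→W₂ at k₄) with death rates k₅,
k₆. This is the unique linear structure whose proliferative block has
trace −(k₃+k₄) and determinant k₃k₄ − k₁k₂, giving the closed-form
spectrum

    λ₁,₂ = [−(k₃+k₄) ± √((k₃+k₄)² − 4(k₃k₄ − k₁k₂))]/2,
    λ₃ = −k₅, λ₄ = −k₆,

always real (the discriminant equals (k₃−k₄)² + 4k₁k₂). The regime is
classified by the sign of `k₁k₂ − k₃k₄` with tolerance 1e−12; under
balance the steady proportions are M/I = k₂/k₄ = k₃/k₁, W₂/M = k₄/k₆,
W₁/I = k₃/k₅ (the left-eigenvector/null-space ratios of the generator).
A direct corollary, asserted in tests: with differentiation along only
one lineage (k₃ = 0 or k₄ = 0) and positive division rates, λ₁ > 0 —
no balanced steady state exists.

Trajectories are computed as `x(t) = expm(A t) x₀` (exact up to matrix-
exponential accuracy, no time-stepping error; the generator's Metzler
structure preserves nonnegativity). k₁ is the natural time unit; with
k₁ = 1, setting `k₂ = λ(c)²` makes the leading eigenvalue √(k₁k₂)
equal the discrete model's limiting M/I for maturation period c. The
tests confirm this correspondence for c = 1..6 to 1e−6 against the
exact integer ratio at t = 300.

## Numerical choices

- Root-finding for ρ and λ uses plain bisection on the bracketed,
  monotone intervals (1, 2] and (0, 1] to an interval width of 1e−13;
  both residuals are monotone on their brackets, so convergence is
  guaranteed.
- `c_from_lambda` is the closed form `1 − ln λ / ln(1+λ)`, with the
  λ = 1 ↦ c = 1 limit handled explicitly.
- The `n_wm(g)` schedule is floored at `c`; behaviour below that floor
  is not otherwise defined by the rules, and the floor keeps the
  division count nonnegative, consistent with the rule that a cell with
  `n_wm = c` skips the mature stage.
- Ages advance for all non-dead cells, including wholly mature cells —
  required for lifespan-driven death at the structure's edge.
- Compartment sizes and rates are validated nonnegative; `k₁ > 0` is
  required (it sets the time unit).

## Problem sizes in the test suite

Agent-based cross-checks against the exact recurrence cap the simulated
population at roughly 2·10⁵ cells (horizons t ≤ 17 for c = 1, t ≤ 25
for c = 2, t ≤ 30 otherwise); spatial/linear count-equivalence uses
horizons 13–20 by c; the steady-state configuration runs to t = 210
(six lifespans). Long-time ratios (t = 300) go through the exact
integer recurrence rather than agents, whose population (~10³³ cells)
is far beyond simulation. These sizes are deep in the asymptotic regime
for every quantity asserted.

## Limitations

- The model is fully deterministic: no stochastic division timing, no
  cell-cycle dispersion, no mechanics, curvature, signalling feedback
  or crypt fission. Agreement of the printed tables and ratios shows
  internal consistency of the rule set, not biological calibration.
- The spatial placement rule reproduces counts, leaflet number and
  approximate rotational organization; cell-for-cell identity with any
  particular rendering of the structure is not claimed.
- The star-lattice position keying is exact in practice for the
  supported rotation increments at simulated sizes, but is not a
  general-purpose exact lattice for arbitrary D.
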