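# Methods

`groupchase` simulates a population of predators ("chasers") pursuing
faster, fleeing prey ("targets") in a two-dimensional disk habitat, and
measures when a costly cooperative pursuit rule can out-compete a selfish
one — as a population, inside mixed pursuit groups, and under social
learning.

## The model

**Habitat.** A disk of radius `R = 500` centred at the origin.  A disk is
used (rather than a square) because corners trap prey; the boundary is a
smooth hazard that prey avoid.  Space and time are continuous; agents move
in straight sub-steps of one time unit (`delta_t = 1`), interpreted as the
minimum time of inertial linear motion.

**Targets** (`N_T = 50`, speed `v_T = 0.1`).  A target watches for the
nearest *hazard* — any chaser, or the boundary — within recognition range
`r_haz = 50`.  If one is in range it flees straight away from it
(from the boundary's nearest point, this means inward); otherwise it
performs a random walk.  A captured target is replaced immediately at a
uniformly random position at least `r_min` from every agent, so the
population size never changes.

**Chasers** (`N_C = 100`) carry one of two strategies:

* **DCS** (direct chasing strategy): move straight toward the nearest
  target at speed `v_D` (swept over 0.072–0.098);
* **GCS** (group chasing strategy): with `T_k` the nearest target at
  distance `d`, and Gamma the set of *other* chasers not farther than `d`
  from `T_k` (closed comparison, both strategies, and — by default — both
  activity modes), steer toward the aim point

      X = (n+1) r_T − Σ_{j in Gamma} r_Cj ,   n = |Gamma|,

  i.e. the point that would put the target at the centroid of the chaser
  and its group.  This can point *away* from the target.  GCS moves at
  `v_G = 0.07 < v_D`: the cognitive cost of cooperation.  With an empty
  group the rule collapses exactly to DCS.

The speed ordering `v_G < v_D < v_T` is enforced: prey outrun everyone,
so captures require cornering or encirclement, never tail-chasing.

**Hunt/rest cycle.** Each chaser alternates between hunting and resting
(resting = random walk at its strategy speed).  After `t` time units in a
mode the per-step probability of leaving it is `min(t/T, 1)` with
`T_hunt = T_rest = 1e3`.  The timer of the active mode increments *after*
the draw, so a spell survives its first draw with certainty when entered
fresh; the linear hazard makes typical spells O(sqrt(T)) ≈ 40 steps and
caps them at `T` steps.  Capturing does not reset the hunting clock.

**One step** (all proposals computed from start-of-step positions):
mode draws → pursuing-set snapshot → chaser proposals (a hunting chaser
whose nearest target lies within one step snaps exactly onto it) → target
proposals → chasers commit in a uniformly random order, a move rejected if
it lands strictly within `r_min = 0.15` of any other chaser's current
position → targets commit in a uniformly random order, with capture
(distance ≤ `eps_capture = 1e-6` to an updated hunting chaser; the nearest
such chaser is credited, ties to the lowest id) and replacement →
(learning variant) imitation → `t += delta_t`.

**Variants.** `A_DCS`/`A_GCS`: homogeneous populations.  `B`: 50/50 mix,
strategies frozen.  `C`: as B, plus learning — after every capture, all
chasers within `r_learn = 200` of the capture location adopt the
capturer's current strategy; within a step, events are applied in capture
order, so a freshly converted capturer propagates its new strategy.
Homogeneous populations are absorbing ("fixation").

## Observables

* **Hunting performance** `h(t)`: captures per chaser in non-overlapping
  windows of width `2e4` centred at `t`.  In the mixed model it is
  stratified by strategy and by set category (homogeneous vs
  heterogeneous); the denominator is the *time-averaged* number of
  strategy-s chasers in category-c sets over the window, and empty
  denominators yield NaN, never 0.
* **Sets**: chasers grouped by nearest target.  By default resting
  chasers count as members of their nearest target's set
  (`resting_chasers_in_sets=True`); only this inclusive convention
  reproduces the published per-class fitness values (under the
  hunting-only reading, the lone-defector fitness f_D(1,2) comes out
  ~5 standard errors below the published 2.0; inclusively it matches).
  The convention is a pure observable — it never feeds back into the
  dynamics — and the exclusive reading remains available as a switch.
  The snapshot is taken after the mode draw and before any movement, so
  the eventual capturer of a step is always a member of its target's
  set.
* **Set-resolved fitness** (see `observables` module docstring): a
  strategy's capture share over its occupancy share per (n_G, n_D) class,
  accumulated over a steady-state window (default [5e5, 9e5] at the full
  horizon).  The occupancy-weighted mean of all defined fitnesses is 1 by
  construction — an exact identity the tests enforce on every table.
* **Switch ("Nash") analysis**: a G→D arrow at (g, d) when
  f_G(g,d) < f_D(g−1,d+1), symmetrically D→G; cells where every defined
  comparison fails are equilibrium cells; comparisons touching undefined
  fitness are reported as skipped and the cell is not called stable.
* **Fixation**: first time the strategy counts hit 0 or N_C; ensemble
  fixation probabilities with binomial standard errors.

## Numerical and design choices

* **Two engines, one contract.** A readable pure-Python reference step
  and a numba kernel consume one shared `np.random.Generator` in an
  identical draw order (mode draws; proposals in agent-index order; one
  Fisher–Yates shuffle per species per step; two uniforms per placement
  attempt).  Norms are written `sqrt(x*x + y*y)` and nearest-entity scans
  compare squared distances in both, so the two engines are *bitwise*
  identical — enforced by the test suite over ten seeds, including
  capture, replacement and learning events.  The kernel's stamped
  uniform grid (cell 2.0 ≫ every interaction radius plus two step
  lengths) only prunes provably impossible candidates.
* **Boundary**: a proposed position outside the disk is clamped radially
  onto the circle.  Fleeing targets turn inward within `r_haz`, so
  clamping is a rare safety net.
* **Degenerate directions** (target exactly on its hazard; a GCS aim
  point coinciding with the chaser): a uniformly random unit vector —
  any fixed choice would bias the symmetric case.
* **Ties** (equidistant targets or hazards): lowest agent id; the
  boundary loses against a chaser.  Ties have measure zero; the rule
  exists for deterministic replay.
* **Capture tolerance** `1e-6`: the snap rule copies coordinates exactly,
  so the tolerance only absorbs floating-point transport error and sits
  far below `r_min`.
* **Initial state**: agents placed by rejection sampling with same-species
  separation ≥ `r_min` (cross-species overlap is legal and resolved only
  by capture); all chasers start hunting with zeroed timers; mixed models
  assign `round(f·N_C)` GCS to a uniformly random subset.
* **Event timestamps**: captures carry the start time of their step, and
  the steady-state window filters set snapshots and captures with the
  same predicate — this is what makes the fitness normalization identity
  exact rather than approximate at window edges.
* **Early stop at fixation** (optional): fixation freezes the strategy
  counts, so ending a run there cannot change fixation statistics; used
  only for fixation-probability ensembles.

## What the tests establish — and what they cannot

The published experiments average 1000–5000 runs of 1e6 steps; the test
suite scales this down to fit a desk budget (about 2×10^7 simulated steps
in total, fixed a priori from engine throughput, seeds frozen in advance).
At the published densities captures are rare (~2.6×10^-4 per step in the
mixed model), which sets the attainable precision:

* The *population ordering* (the cooperative population out-hunting every
  direct population: at 5 runs × 3e5 the gap is ~4×, far beyond its
  standard error) and *fixation direction* (20 learning runs) are well
  resolved and tested.
* The *within-set orderings* and the *printed per-class fitness values*
  are measured on a 10-run ensemble at the full published per-run
  protocol (1e6 steps, steady window [5e5, 9e5]); only the ensemble is
  scaled down.  The heterogeneous-set advantage of direct chasers at
  v_D = 0.082 needs that window — it has not yet developed by t ≈ 4e5 —
  while the homogeneous-set advantage of group chasers is a small effect
  that 10 runs may not resolve (the published version uses 1000).  The
  rarest printed fitness classes collect only ~10–25 captures here
  (Monte-Carlo s.e. 0.2–0.5 on values of order 1–2), so the ±0.2 band is
  at or beyond the attainable precision for some cells; a red outcome
  there measures sampling precision, not necessarily model disagreement.
* The *equal-speed null calibration* (v_D = v_G under a test-only flag)
  does **not** drive every per-class fitness to 1, and the suite
  documents this honestly: per-capita capture propensity depends on set
  class (captures are largely per-target events shared among a set's
  occupants, so small sets over-perform per capita).  Equalizing speeds
  equalizes chaser ability *within* a class, not across classes; only the
  occupancy-weighted mean of the fitness surface is pinned to 1, exactly,
  by construction.

## Known limitations

* Chasers are omniscient about target positions (no vision cone) and
  prey recognize hazards isotropically — both inherited from the model.
* No birth–death demography, energy budget, or prey handling time beyond
  the two-mode clock.
* The fitness surface at large set sizes (n_G + n_D ≳ 10) is sparsely
  sampled at any feasible scale; the analysis tools report such cells as
  undefined rather than extrapolating.
* With `delta_t` ≠ 1 the engines remain exact and equivalent, but the
  published parameter set assumes unit steps; window and bin edges are
  treated as closed intervals on step-start times.
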