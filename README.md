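# groupchase

Agent-based simulation of **group chase and escape** in a two-dimensional
disk habitat, built to study a social dilemma in foraging: when does a
*cooperative* pursuit strategy beat a *selfish* one, and can it take over
a population through learning?

A population of `N_C = 100` chasers hunts `N_T = 50` faster, fleeing
targets (speed `v_T = 0.1`).  Targets flee the nearest hazard — a chaser
or the habitat boundary — within recognition range `r_haz = 50`, and are
replaced at a random location when captured.  Chasers alternate between
hunting and resting, and carry one of two strategies:

* **DCS** (direct chasing): move straight at the nearest target `T_j`,

      v̂ = (r_Tj − r_C) / |r_Tj − r_C|,          speed v_D ∈ [0.072, 0.098]

* **GCS** (group chasing): with Γ the other chasers at least as close to
  the nearest target `T_k`, steer toward the aim point

      X = (n+1)·r_Tk − Σ_{j∈Γ} r_Cj,   n = |Γ|,   speed v_G = 0.07 < v_D

  — the point that would place the target at the group's centroid, even
  if that means moving *away* from it.  Cooperation costs speed:
  `v_G < v_D < v_T`.

Three experiments are built in: homogeneous populations (is encirclement
better for the group?), a 50/50 mix without learning (who profits inside
a mixed pursuit set?), and the mix with spatial imitation learning
(which strategy *fixes*?).  The headline phenomenon is a multi-player
social dilemma: the cooperative population out-hunts every direct
population, direct chasers out-earn cooperators inside mixed sets — and
learning from successful neighbours nevertheless drives the population
to cooperation at slow defector speeds.

## Worked example

```python
import groupchase as gc

cfg = gc.SimulationConfig(model="B", v_D=0.082, T_max=5e4, seed=1)
result = gc.run_simulation(cfg, window=(2e4, 5e4))
print(result.captures.head())
```

Running `python examples/quickstart_single_run.py` prints:

```
simulated 50000 steps with 100 chasers / 50 targets
total captures: 10 (GCS 7, DCS 3)

first few capture events:
      t  chaser_id  strategy  target_id           x           y  n_G  n_D
 1952.0         31         1          2  -44.094679 -422.077090    2    1
 9279.0         33         1          6 -244.067744 -402.879903    5    7
15937.0         37         1         19  260.620402  176.088571    1    2
17750.0         53         0          4  213.718330  352.832062    1    6
20197.0         29         1          2 -291.046525  -55.118893    4    0
```

Each capture records who caught what, where, and the `(n_G, n_D)`
composition of the pursuing set — the raw material for the set-resolved
fitness `f_s(n_G, n_D)`: strategy *s*'s share of captures in that set
class divided by its share of chaser observations (1.0 = average
ability; the occupancy-weighted mean is exactly 1 by construction).
Captures are rare events at these densities (prey outrun predators, so
kills need cornering or encirclement) — the published protocols average
1000+ runs of 10^6 steps, and the `examples/` scripts note where they
are scaled down.

Other entry points: `examples/model_a_performance.py` (population-level
comparison), `examples/model_b_fitness.py` (stratified hunting
performance, fitness table, equilibrium arrows),
`examples/model_c_fixation.py` (fixation probabilities under learning),
`examples/animate_run.py` (GIF of a small world).  The library surface
is `SimulationConfig`, `run_simulation`, `run_ensemble`, the
`observables` module, and the packaged protocols in
`groupchase.recipes`; see `docs/methods.md` for the full model
description and numerical choices.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch — a mixed-population
ensemble with set-resolved fitness statistics (including the exact
fitness-normalization identity) and a learning ensemble with fixation
detection — and writes the target report to the given path.
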