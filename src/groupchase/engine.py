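"""Per-step update loop and run drivers.

One simulation step executes, in this order:

1. every chaser draws its hunt/rest mode switch (timers advance);
2. the pursuing-set snapshot is taken (hunting chasers grouped by nearest
   target, with start-of-step positions) — it classifies this step's
   captures and feeds the set statistics;
3. all chasers compute attempted positions (resting: random walk;
   hunting: snap onto the nearest target if it is within one step's
   reach, otherwise one straight sub-step along the strategy direction);
4. all targets compute attempted positions (flee the nearest hazard, or
   random walk);
5. chasers commit in a uniformly random order, each move rejected if it
   would land within ``r_min`` of any other chaser's current position;
6. targets commit in a uniformly random order; a target coinciding (to
   within ``eps_capture``) with an updated hunting chaser is captured and
   replaced by a fresh target at least ``r_min`` from every agent;
7. (learning variant only) chasers within ``r_learn`` of a capture adopt
   the capturer's strategy;
8. time advances by ``delta_t``.

Two interchangeable engines exist: this module's readable pure-Python
implementation and the numba kernel in :mod:`groupchase._kernel`.  They
consume the shared random stream in an identical order and produce
bitwise-identical world states — a property the test suite enforces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CaptureEvent,
    Mode,
    Model,
    PlacementError,
    SimulationConfig,
    Strategy,
    WorldState,
    clamp_to_disk,
    random_unit_vector,
)
from .kinematics import (
    _dist2,
    dcs_direction,
    gcs_direction,
    nearest_target_index,
    target_direction,
)
from .modes import advance_mode

__all__ = [
    "ProposedMove",
    "StepReport",
    "RunResult",
    "EnsembleResult",
    "initialize_world",
    "propose_chaser_move",
    "propose_target_move",
    "commit_chaser_moves",
    "commit_target_moves_and_captures",
    "apply_learning",
    "step",
    "run_simulation",
    "run_ensemble",
    "set_snapshot_counts",
    "DEFAULT_WINDOW",
    "DEFAULT_BIN_WIDTH",
]

#: steady-state measurement window used for set statistics (time units)
DEFAULT_WINDOW = (5e5, 9e5)
#: width of the centred windows for the hunting-performance series h(t)
DEFAULT_BIN_WIDTH = 2e4

CAPTURE_COLUMNS = ["t", "chaser_id", "strategy", "target_id", "x", "y",
                   "n_G", "n_D"]
_CAPTURE_DTYPES = {"t": np.float64, "chaser_id": np.int32,
                   "strategy": np.int64, "target_id": np.int32,
                   "x": np.float64, "y": np.float64,
                   "n_G": np.int64, "n_D": np.int64}


def captures_frame(rows) -> pd.DataFrame:
    """Capture log DataFrame with canonical column dtypes."""
    df = pd.DataFrame(rows, columns=CAPTURE_COLUMNS)
    return df.astype(_CAPTURE_DTYPES)


@dataclass
class ProposedMove:
    agent_id: int
    species: str  # "CHASER" | "TARGET"
    attempted_pos: np.ndarray
    snap_target_id: Optional[int] = None


@dataclass
class StepReport:
    t: float
    captures: list[CaptureEvent] = field(default_factory=list)
    learning_updates: list[tuple[int, Strategy, Strategy]] = field(
        default_factory=list)
    rejected_moves: dict = field(default_factory=lambda: {"CHASER": 0,
                                                          "TARGET": 0})
    # pursuing-set decomposition taken inside the step (post mode draw,
    # pre movement): per-target GCS / DCS pursuer counts
    set_g: Optional[np.ndarray] = None
    set_d: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _place_apart(rng, R, r_min, others: list[np.ndarray],
                 max_attempts: int) -> np.ndarray:
    """Rejection-sample a uniform disk point >= r_min from every listed
    position."""
    from .core import uniform_point_in_disk
    r2 = r_min * r_min
    for _ in range(max_attempts):
        p = uniform_point_in_disk(rng, R)
        ok = True
        for q in others:
            if _dist2(p, q) < r2:
                ok = False
                break
        if ok:
            return p
    raise PlacementError(
        f"placement failure after {max_attempts} attempts")


def initialize_world(cfg: SimulationConfig,
                     rng: Optional[np.random.Generator] = None) -> WorldState:
    """Place all agents and assign strategies.

    Chasers are placed first, then targets, each by rejection sampling so
    that same-species pairs are at least ``r_min`` apart (cross-species
    overlap is allowed; only the capture rule resolves it).  For the mixed
    models a uniformly random subset of ``round(f * N_C)`` chasers starts
    as GCS.  Everybody starts in HUNT mode with zeroed timers.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chaser_pos: list[np.ndarray] = []
    for _ in range(cfg.N_C):
        chaser_pos.append(_place_apart(rng, cfg.R, cfg.r_min, chaser_pos,
                                       cfg.max_placement_attempts))
    target_pos: list[np.ndarray] = []
    for _ in range(cfg.N_T):
        target_pos.append(_place_apart(rng, cfg.R, cfg.r_min, target_pos,
                                       cfg.max_placement_attempts))

    strategy = np.full(cfg.N_C, Strategy.DCS, dtype=np.int8)
    n_gcs = cfg.n_gcs_initial
    if 0 < n_gcs <= cfg.N_C:
        perm = _fisher_yates(rng, cfg.N_C)
        strategy[perm[:n_gcs]] = Strategy.GCS

    return WorldState(
        t=0.0,
        chaser_pos=np.asarray(chaser_pos, dtype=np.float64),
        chaser_strategy=strategy,
        chaser_mode=np.full(cfg.N_C, Mode.HUNT, dtype=np.int8),
        t_hunt=np.zeros(cfg.N_C),
        t_rest=np.zeros(cfg.N_C),
        target_pos=np.asarray(target_pos, dtype=np.float64),
        rng=rng,
    )


def _fisher_yates(rng: np.random.Generator, n: int) -> np.ndarray:
    """In-house shuffle consuming one uniform per swap; the compiled
    kernel replays the identical sequence."""
    perm = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = int(rng.random() * (i + 1))
        perm[i], perm[j] = perm[j], perm[i]
    return perm


# ---------------------------------------------------------------------------
# snapshot
# ---------------------------------------------------------------------------

def set_snapshot_counts(world: WorldState, include_resting: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-target (GCS count, DCS count) of hunting chasers whose nearest
    target is that target — the pursuing-set decomposition."""
    n_g = np.zeros(world.n_targets, dtype=np.int64)
    n_d = np.zeros(world.n_targets, dtype=np.int64)
    for i in range(world.n_chasers):
        if world.chaser_mode[i] != Mode.HUNT and not include_resting:
            continue
        k = nearest_target_index(world.chaser_pos[i], world)
        if world.chaser_strategy[i] == Strategy.GCS:
            n_g[k] += 1
        else:
            n_d[k] += 1
    return n_g, n_d


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------

def propose_chaser_move(chaser, world: WorldState, cfg: SimulationConfig,
                        rng: np.random.Generator) -> ProposedMove:
    """Attempted position of one chaser whose mode is already advanced."""
    speed = cfg.chaser_speed(chaser.strategy) * cfg.delta_t
    snap_id = None
    if chaser.mode == Mode.REST:
        att = chaser.pos + speed * random_unit_vector(rng)
    else:
        k = nearest_target_index(chaser.pos, world)
        d2 = _dist2(world.target_pos[k], chaser.pos)
        if d2 <= speed * speed:
            att = world.target_pos[k].copy()
            snap_id = k
        elif chaser.strategy == Strategy.GCS:
            att = chaser.pos + speed * gcs_direction(chaser, world, rng, cfg)
        else:
            att = chaser.pos + speed * dcs_direction(chaser, world)
    return ProposedMove(chaser.id, "CHASER", clamp_to_disk(att, cfg.R),
                        snap_id)


def propose_target_move(target, world: WorldState, cfg: SimulationConfig,
                        rng: np.random.Generator) -> ProposedMove:
    speed = cfg.v_T * cfg.delta_t
    att = target.pos + speed * target_direction(target, world, cfg, rng)
    return ProposedMove(target.id, "TARGET", clamp_to_disk(att, cfg.R))


# ---------------------------------------------------------------------------
# commits
# ---------------------------------------------------------------------------

def commit_chaser_moves(world: WorldState, proposals: Sequence[ProposedMove],
                        cfg: SimulationConfig, rng: np.random.Generator,
                        report: Optional[StepReport] = None) -> WorldState:
    """Commit chaser moves in a uniformly random order with same-species
    exclusion: a move landing strictly within ``r_min`` of any *other*
    chaser's current (possibly already updated) position is rejected and
    the chaser stays put (its snap is voided)."""
    r2 = cfg.r_min * cfg.r_min
    order = _fisher_yates(rng, world.n_chasers)
    for idx in order:
        att = proposals[idx].attempted_pos
        blocked = False
        for m in range(world.n_chasers):
            if m != idx and _dist2(att, world.chaser_pos[m]) < r2:
                blocked = True
                break
        if blocked:
            proposals[idx].snap_target_id = None
            if report is not None:
                report.rejected_moves["CHASER"] += 1
        else:
            world.chaser_pos[idx] = att
    return world


def commit_target_moves_and_captures(
    world: WorldState, proposals: Sequence[ProposedMove],
    cfg: SimulationConfig, rng: np.random.Generator,
    set_g: Optional[np.ndarray] = None, set_d: Optional[np.ndarray] = None,
    report: Optional[StepReport] = None,
) -> tuple[WorldState, list[CaptureEvent]]:
    """Process targets in a uniformly random order.

    A target with an updated hunting chaser within ``eps_capture`` of its
    current (pre-move) position is captured: the nearest such chaser (tie
    to the lowest id) is credited, and a replacement target appears
    uniformly at random at least ``r_min`` from every agent.  Survivors
    move to their attempted position unless another target's current
    position is strictly within ``r_min`` of it.
    """
    eps2 = cfg.eps_capture * cfg.eps_capture
    r2 = cfg.r_min * cfg.r_min
    captures: list[CaptureEvent] = []
    order = _fisher_yates(rng, world.n_targets)
    for j in order:
        tp = world.target_pos[j]
        best_i, best_d2 = -1, math.inf
        for i in range(world.n_chasers):
            if world.chaser_mode[i] != Mode.HUNT:
                continue
            d2 = _dist2(world.chaser_pos[i], tp)
            if d2 <= eps2 and d2 < best_d2:
                best_i, best_d2 = i, d2
        if best_i >= 0:
            ev = CaptureEvent(
                t=world.t,
                chaser_id=best_i,
                chaser_strategy=Strategy(int(world.chaser_strategy[best_i])),
                target_id=j,
                pos=tp.copy(),
                n_G=int(set_g[j]) if set_g is not None else 0,
                n_D=int(set_d[j]) if set_d is not None else 0,
            )
            captures.append(ev)
            others = ([world.chaser_pos[i] for i in range(world.n_chasers)]
                      + [world.target_pos[m] for m in range(world.n_targets)
                         if m != j])
            world.target_pos[j] = _place_apart(
                rng, cfg.R, cfg.r_min, others, cfg.max_placement_attempts)
        else:
            att = proposals[j].attempted_pos
            blocked = False
            for m in range(world.n_targets):
                if m != j and _dist2(att, world.target_pos[m]) < r2:
                    blocked = True
                    break
            if blocked:
                if report is not None:
                    report.rejected_moves["TARGET"] += 1
            else:
                world.target_pos[j] = att
    return world, captures


def apply_learning(world: WorldState, captures: Sequence[CaptureEvent],
                   cfg: SimulationConfig
                   ) -> tuple[WorldState, list[tuple[int, Strategy, Strategy]]]:
    """Imitation step (learning variant only): every chaser within
    ``r_learn`` of a capture location adopts the capturer's strategy *as
    of the moment the event is processed* — a capturer converted by an
    earlier event in the same step propagates its new strategy."""
    updates: list[tuple[int, Strategy, Strategy]] = []
    if cfg.model is not Model.C:
        return world, updates
    rl2 = cfg.r_learn * cfg.r_learn
    for ev in captures:
        s = np.int8(world.chaser_strategy[ev.chaser_id])
        for i in range(world.n_chasers):
            if _dist2(world.chaser_pos[i], ev.pos) <= rl2:
                old = world.chaser_strategy[i]
                if old != s:
                    updates.append((i, Strategy(int(old)), Strategy(int(s))))
                world.chaser_strategy[i] = s
    return world, updates


# ---------------------------------------------------------------------------
# one full step
# ---------------------------------------------------------------------------

def step(world: WorldState, cfg: SimulationConfig) -> tuple[WorldState,
                                                            StepReport]:
    """Execute one complete update (mutates ``world`` in place)."""
    rng = world.rng
    report = StepReport(t=world.t)

    for i in range(world.n_chasers):
        c = world.chaser(i)
        advance_mode(c, cfg, rng)
        world.chaser_mode[i] = c.mode
        world.t_hunt[i] = c.t_hunt
        world.t_rest[i] = c.t_rest

    set_g, set_d = set_snapshot_counts(world, cfg.resting_chasers_in_sets)
    report.set_g, report.set_d = set_g, set_d

    chaser_props = [propose_chaser_move(world.chaser(i), world, cfg, rng)
                    for i in range(world.n_chasers)]
    target_props = [propose_target_move(world.target(j), world, cfg, rng)
                    for j in range(world.n_targets)]

    commit_chaser_moves(world, chaser_props, cfg, rng, report)
    _, captures = commit_target_moves_and_captures(
        world, target_props, cfg, rng, set_g, set_d, report)
    report.captures = captures

    _, report.learning_updates = apply_learning(world, captures, cfg)

    world.t = world.t + cfg.delta_t
    return world, report


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Everything one run records.

    ``captures`` is the full capture log; ``class_N/HG/HD`` accumulate the
    set statistics over the steady-state ``window`` (class ``[g, d]`` of
    the arrays is the (n_G, n_D) set class); ``occupancy`` holds, per
    h(t) bin, the summed per-step counts of chasers by (strategy x
    homogeneous/heterogeneous category), with ``occupancy_steps`` snapshots
    per bin, so column sums divided by ``occupancy_steps`` are the
    time-averaged denominators of the stratified hunting performance.
    """

    config: SimulationConfig
    seed: int
    n_steps: int
    captures: pd.DataFrame
    series_t: np.ndarray
    series_n_gcs: np.ndarray
    class_N: np.ndarray
    class_HG: np.ndarray
    class_HD: np.ndarray
    window: tuple[float, float]
    bin_width: float
    occupancy: np.ndarray        # (n_bins, 4): G_het, D_het, G_hom, D_hom
    occupancy_steps: np.ndarray  # (n_bins,)
    fixation_outcome: str        # "GCS" | "DCS" | "none"
    fixation_time: Optional[float]
    final_world: Optional[WorldState] = None

    @property
    def bin_centers(self) -> np.ndarray:
        n = len(self.occupancy_steps)
        return (np.arange(n) + 0.5) * self.bin_width


OCC_COLUMNS = ["G_het", "D_het", "G_hom", "D_hom"]


@dataclass
class EnsembleResult:
    """Independent runs with consecutive seeds and their pooled set
    statistics (order-independent sums)."""

    runs: list[RunResult]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def class_N(self) -> np.ndarray:
        return np.sum([r.class_N for r in self.runs], axis=0)

    @property
    def class_HG(self) -> np.ndarray:
        return np.sum([r.class_HG for r in self.runs], axis=0)

    @property
    def class_HD(self) -> np.ndarray:
        return np.sum([r.class_HD for r in self.runs], axis=0)

    @property
    def captures(self) -> pd.DataFrame:
        frames = []
        for k, r in enumerate(self.runs):
            df = r.captures.copy()
            df.insert(0, "run", k)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @property
    def fixation_outcomes(self) -> list[str]:
        return [r.fixation_outcome for r in self.runs]


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _classify_occupancy(set_g: np.ndarray, set_d: np.ndarray) -> np.ndarray:
    out = np.zeros(4, dtype=np.float64)
    for j in range(len(set_g)):
        g, d = set_g[j], set_d[j]
        if g > 0 and d > 0:
            out[0] += g
            out[1] += d
        elif g > 0:
            out[2] += g
        elif d > 0:
            out[3] += d
    return out


def run_simulation(
    cfg: SimulationConfig,
    *,
    engine: str = "fast",
    window: Optional[tuple[float, float]] = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    sample_every: int = 1000,
    observers: Sequence[Callable[[WorldState, StepReport], None]] = (),
    keep_final_world: bool = False,
    stop_at_fixation: bool = False,
) -> RunResult:
    """Run one simulation from t = 0 until t exceeds ``T_max``.

    Parameters
    ----------
    engine:
        ``"fast"`` (numba kernel) or ``"reference"`` (readable pure-Python
        loop; identical output, orders of magnitude slower).
    window:
        steady-state window for the set statistics; defaults to
        [5e5, 9e5] intersected with the run's horizon.
    bin_width:
        width of the h(t) bins (default 2e4).
    sample_every:
        stride (in steps) of the strategy-count time series.
    observers:
        reference engine only: callables invoked after every step with
        ``(world, report)``.
    stop_at_fixation:
        end the run right after the strategy population absorbs at
        all-GCS or all-DCS.  Every statistic up to that point (and the
        fixation outcome itself, which can never change afterwards) is
        unaffected; use for fixation-probability ensembles only, since
        later-window set statistics are truncated.
    """
    if window is None:
        window = (min(DEFAULT_WINDOW[0], cfg.T_max),
                  min(DEFAULT_WINDOW[1], cfg.T_max))
    n_steps = int(math.floor(cfg.T_max / cfg.delta_t))
    rng = np.random.default_rng(cfg.seed)
    world = initialize_world(cfg, rng)

    if engine == "fast":
        if observers:
            raise ValueError("observers require engine='reference'")
        from ._kernel import run_kernel
        return run_kernel(world, cfg, n_steps, window, bin_width,
                          sample_every, keep_final_world, stop_at_fixation)
    if engine != "reference":
        raise ValueError(f"unknown engine {engine!r}")

    n_bins = max(1, int(math.ceil(n_steps * cfg.delta_t / bin_width)))
    occupancy = np.zeros((n_bins, 4))
    occ_steps = np.zeros(n_bins, dtype=np.int64)
    side = cfg.N_C + 1
    class_N = np.zeros((side, side), dtype=np.int64)
    class_HG = np.zeros((side, side), dtype=np.int64)
    class_HD = np.zeros((side, side), dtype=np.int64)
    cap_rows: list[tuple] = []
    series_t = [0.0]
    series_n = [world.n_gcs]
    fix_outcome, fix_time = _check_fixation(world.n_gcs, cfg.N_C, 0.0)
    n_loop = 0 if (stop_at_fixation and fix_outcome != "none") else n_steps

    for s in range(n_loop):
        t = world.t
        world, report = step(world, cfg)

        b = min(int(t / bin_width), n_bins - 1)
        occupancy[b] += _classify_occupancy(report.set_g, report.set_d)
        occ_steps[b] += 1
        in_window = window[0] <= t <= window[1]
        if in_window:
            for j in range(world.n_targets):
                g, d = report.set_g[j], report.set_d[j]
                if g + d >= 1:
                    class_N[g, d] += 1
        for ev in report.captures:
            cap_rows.append((ev.t, ev.chaser_id, int(ev.chaser_strategy),
                             ev.target_id, ev.pos[0], ev.pos[1],
                             ev.n_G, ev.n_D))
            if in_window:
                if ev.chaser_strategy == Strategy.GCS:
                    class_HG[ev.n_G, ev.n_D] += 1
                else:
                    class_HD[ev.n_G, ev.n_D] += 1

        for obs in observers:
            obs(world, report)
        if fix_outcome == "none":
            fix_outcome, fix_time = _check_fixation(world.n_gcs, cfg.N_C,
                                                    world.t)
        if (s + 1) % sample_every == 0:
            series_t.append(world.t)
            series_n.append(world.n_gcs)
        if stop_at_fixation and fix_outcome != "none":
            break

    if series_t[-1] != world.t:
        series_t.append(world.t)
        series_n.append(world.n_gcs)

    captures = captures_frame(cap_rows)
    return RunResult(
        config=cfg, seed=cfg.seed, n_steps=n_steps, captures=captures,
        series_t=np.asarray(series_t), series_n_gcs=np.asarray(series_n),
        class_N=class_N, class_HG=class_HG, class_HD=class_HD,
        window=window, bin_width=bin_width, occupancy=occupancy,
        occupancy_steps=occ_steps, fixation_outcome=fix_outcome,
        fixation_time=fix_time,
        final_world=world if keep_final_world else None,
    )


def _check_fixation(n_gcs: int, n_c: int, t: float) -> tuple[str,
                                                             Optional[float]]:
    if n_gcs == n_c:
        return "GCS", t
    if n_gcs == 0:
        return "DCS", t
    return "none", None


def run_ensemble(
    cfg: SimulationConfig,
    n_runs: int,
    base_seed: Optional[int] = None,
    **kwargs,
) -> EnsembleResult:
    """Run ``n_runs`` independent simulations with seeds
    ``base_seed .. base_seed + n_runs - 1`` (default base: ``cfg.seed``)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if base_seed is None:
        base_seed = cfg.seed
    runs = [run_simulation(cfg.with_(seed=base_seed + k), **kwargs)
            for k in range(n_runs)]
    return EnsembleResult(runs=runs)
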