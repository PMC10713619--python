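"""Pure direction rules for targets and chasers.

All functions return unit vectors (or assessments) computed from the
current world state; none of them mutates state.  Nearest-entity ties are
broken by lowest agent id, and the boundary loses a tie against a chaser —
deterministic replay matters, the tied sets have measure zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    ChaserState,
    PursuitContext,
    SimulationConfig,
    Strategy,
    TargetState,
    WorldState,
    random_unit_vector,
)

__all__ = [
    "HazardKind",
    "HazardAssessment",
    "nearest_hazard",
    "target_direction",
    "nearest_target_index",
    "dcs_direction",
    "pursuit_context",
    "gcs_direction",
]


class HazardKind(enum.Enum):
    NONE = "none"
    CHASER = "chaser"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class HazardAssessment:
    target_id: int
    kind: HazardKind
    pos: Optional[np.ndarray]  # position of the hazard; None when NONE
    distance: float            # +inf when NONE


# Norms are spelled sqrt(x*x + y*y) (not hypot) and nearest-entity scans
# compare *squared* distances: the compiled fast kernel uses exactly these
# expressions, and bitwise agreement between the two engines requires
# identical floating-point operation sequences.

def _norm(v: np.ndarray) -> float:
    x, y = float(v[0]), float(v[1])
    return math.sqrt(x * x + y * y)


def _dist2(a: np.ndarray, b: np.ndarray) -> float:
    dx = float(a[0]) - float(b[0])
    dy = float(a[1]) - float(b[1])
    return dx * dx + dy * dy


def nearest_hazard(
    target: TargetState, world: WorldState, cfg: SimulationConfig
) -> HazardAssessment:
    """Find the nearest hazard of a target within recognition range.

    Hazards are every chaser (distance ``|r_T - r_C|``) and the disk
    boundary (distance ``R - |r_T|``, hazard point at the radial
    projection of the target onto the boundary circle).  Returns a
    ``NONE`` assessment when nothing lies within ``r_haz``.  A target at
    the exact centre has no defined boundary direction, but the boundary
    is then ``R`` away and ``r_haz < R`` excludes it anyway.
    """
    best_i = -1
    best_d2 = math.inf
    for i in range(world.n_chasers):
        if not cfg.resting_chasers_are_hazards and world.chaser_mode[i] != 0:
            continue
        d2 = _dist2(target.pos, world.chaser_pos[i])
        if d2 < best_d2:
            best_d2, best_i = d2, i

    best_kind = HazardKind.NONE
    best_pos: Optional[np.ndarray] = None
    best_d = math.inf
    if best_i >= 0:
        best_kind = HazardKind.CHASER
        best_pos = world.chaser_pos[best_i].copy()
        best_d = math.sqrt(best_d2)

    rt = _norm(target.pos)
    if rt > 0.0:
        d_boundary = cfg.R - rt
        # boundary loses ties against a chaser (strict <)
        if d_boundary < best_d:
            best_d = d_boundary
            best_kind = HazardKind.BOUNDARY
            best_pos = target.pos * (cfg.R / rt)

    if best_d > cfg.r_haz:
        return HazardAssessment(target.id, HazardKind.NONE, None, math.inf)
    return HazardAssessment(target.id, best_kind, best_pos, best_d)


def target_direction(
    target: TargetState,
    world: WorldState,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Flee direction of a target: straight away from its nearest hazard,
    or a uniformly random direction when no hazard is in range (or the
    target sits exactly on the hazard)."""
    hz = nearest_hazard(target, world, cfg)
    if hz.kind is HazardKind.NONE:
        return random_unit_vector(rng)
    away = target.pos - hz.pos
    n = _norm(away)
    if n == 0.0:
        return random_unit_vector(rng)
    return away / n


def nearest_target_index(pos: np.ndarray, world: WorldState) -> int:
    """Index of the target nearest to ``pos``; ties go to the lowest id."""
    best_j, best_d2 = 0, math.inf
    for j in range(world.n_targets):
        d2 = _dist2(world.target_pos[j], pos)
        if d2 < best_d2:
            best_j, best_d2 = j, d2
    return best_j


def dcs_direction(chaser: ChaserState, world: WorldState) -> np.ndarray:
    """Direct pursuit: unit vector from the chaser to its nearest target."""
    j = nearest_target_index(chaser.pos, world)
    to_target = world.target_pos[j] - chaser.pos
    n = _norm(to_target)
    if n == 0.0:  # engine's snap rule fires before this can happen
        return random_unit_vector(world.rng)
    return to_target / n


def pursuit_context(chaser: ChaserState, world: WorldState,
                    cfg: Optional[SimulationConfig] = None) -> PursuitContext:
    """Encirclement context of a group chaser.

    With ``T_k`` the nearest target at distance ``d``, the group Gamma is
    every other chaser not farther than ``d`` from ``T_k`` (closed
    comparison; both strategies and, by default, both modes qualify).
    The aim point is ``(n+1)*r_Tk - sum_{j in Gamma} r_Cj``: stepping onto
    it would place the target at the centroid of the chaser and its group.
    """
    k = nearest_target_index(chaser.pos, world)
    rt = world.target_pos[k]
    d2 = _dist2(rt, chaser.pos)
    gamma = []
    aim = rt.astype(float).copy()
    include_resting = cfg is None or cfg.resting_chasers_in_gamma
    for j in range(world.n_chasers):
        if j == chaser.id:
            continue
        if not include_resting and world.chaser_mode[j] != 0:
            continue
        if _dist2(rt, world.chaser_pos[j]) <= d2:  # closed: "not farther"
            gamma.append(j)
            aim += rt - world.chaser_pos[j]
    return PursuitContext(
        chaser_id=chaser.id, target_id=k, d=math.sqrt(d2),
        gamma=tuple(gamma), n=len(gamma), aim=aim,
    )


def gcs_direction(
    chaser: ChaserState,
    world: WorldState,
    rng: np.random.Generator,
    cfg: Optional[SimulationConfig] = None,
) -> np.ndarray:
    """Group pursuit: unit vector toward the encirclement aim point.

    Reduces exactly to :func:`dcs_direction` when the chaser is strictly
    nearest to its target (empty group).  The chaser may move *away* from
    the target when the group lies beyond it.  A degenerate aim point
    coinciding with the chaser's own position falls back to a random
    direction (any fixed choice would bias the symmetric case).
    """
    ctx = pursuit_context(chaser, world, cfg)
    v = ctx.aim - chaser.pos
    n = _norm(v)
    if n == 0.0:
        return random_unit_vector(rng)
    return v / n
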