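"""Core domain types, configuration validation and disk-habitat geometry.

The habitat is a two-dimensional disk of radius ``R`` centred at the origin.
Two predator ("chaser") strategies coexist:

* **DCS** (direct chasing strategy) — move straight toward the nearest
  target at speed ``v_D``;
* **GCS** (group chasing strategy) — move so that the nearest target ends
  up at the centroid of all chasers at least as close to it, at the reduced
  speed ``v_G`` (the cost of the cooperative computation).

Targets move at ``v_T`` and flee the nearest hazard (chaser or boundary)
within recognition range ``r_haz``.  The speeds must satisfy the strict
ordering ``v_G < v_D < v_T``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Model",
    "Strategy",
    "Mode",
    "SimulationConfig",
    "ConfigError",
    "PlacementError",
    "validate_config",
    "uniform_point_in_disk",
    "clamp_to_disk",
    "random_unit_vector",
    "ChaserState",
    "TargetState",
    "WorldState",
    "PursuitContext",
    "CaptureEvent",
]


class Model(str, enum.Enum):
    """Simulation variant.

    ``A_DCS``/``A_GCS`` are the homogeneous populations (all chasers share
    one strategy), ``B`` mixes both strategies without learning, and ``C``
    adds spatial imitation learning from successful capturers.
    """

    A_DCS = "A_DCS"
    A_GCS = "A_GCS"
    B = "B"
    C = "C"


class Strategy(enum.IntEnum):
    DCS = 0
    GCS = 1


class Mode(enum.IntEnum):
    HUNT = 0
    REST = 1


class ConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an agent within the
    attempt budget (practically impossible at the default densities)."""


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulation run.

    Defaults are the published operating point of the model: a disk of
    radius 500 holding 100 chasers and 50 targets, target speed 0.1,
    GCS speed 0.07, DCS speed swept over [0.072, 0.098], time step 1,
    same-species exclusion radius 0.15, hazard recognition range 50,
    learning radius 200, mode-duration caps T_hunt = T_rest = 1e3 and a
    horizon of 1e6 time units.
    """

    R: float = 500.0
    N_C: int = 100
    N_T: int = 50
    v_T: float = 0.1
    v_D: float = 0.082
    v_G: float = 0.07
    delta_t: float = 1.0
    r_min: float = 0.15
    r_haz: float = 50.0
    r_learn: float = 200.0
    T_hunt: float = 1e3
    T_rest: float = 1e3
    T_max: float = 1e6
    model: Model = Model.B
    initial_gcs_fraction: Optional[float] = None
    seed: int = 0
    eps_capture: float = 1e-6
    max_placement_attempts: int = 100_000
    # Test-only escape hatch: permit v_D == v_G for the equal-ability null
    # calibration (every fitness must then converge to 1).
    relax_speed_ordering: bool = False
    # Sensitivity switches (defaults follow the published model reading):
    # resting chasers still scare targets and still count toward the
    # encirclement group of a GCS chaser.
    resting_chasers_are_hazards: bool = True
    resting_chasers_in_gamma: bool = True
    # Whether a resting chaser still belongs to the pursuing set of its
    # nearest target for the set statistics (pure observable: never
    # affects the dynamics).  The inclusive convention reproduces the
    # published per-class fitness values; set False to count only
    # actively hunting chasers.
    resting_chasers_in_sets: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        if self.initial_gcs_fraction is None:
            frac = {Model.A_DCS: 0.0, Model.A_GCS: 1.0}.get(self.model, 0.5)
            object.__setattr__(self, "initial_gcs_fraction", frac)
        validate_config(self)

    @property
    def n_gcs_initial(self) -> int:
        return int(round(self.initial_gcs_fraction * self.N_C))

    def chaser_speed(self, strategy: Strategy | int) -> float:
        return self.v_G if int(strategy) == Strategy.GCS else self.v_D

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


def validate_config(cfg: SimulationConfig) -> SimulationConfig:
    """Check every configuration invariant; return ``cfg`` unchanged.

    Raises
    ------
    ConfigError
        With message ``"speed-ordering violation"`` if the strict chain
        v_G < v_D < v_T fails, or ``"invalid parameter: ..."`` for
        non-positive lengths/counts or out-of-range fractions.
    """
    def bad(msg: str) -> ConfigError:
        return ConfigError(f"invalid parameter: {msg}")

    for name in ("R", "v_T", "v_D", "v_G", "delta_t", "r_min", "r_haz",
                 "r_learn", "T_hunt", "T_rest"):
        if not getattr(cfg, name) > 0:
            raise bad(f"{name} must be > 0")
    if cfg.N_C < 1 or cfg.N_T < 1:
        raise bad("N_C and N_T must be >= 1")
    if cfg.T_max < cfg.delta_t:
        raise bad("T_max must be >= delta_t")
    if not (cfg.r_min < cfg.r_haz < cfg.R):
        raise bad("need r_min < r_haz < R")
    if cfg.relax_speed_ordering:
        if not (cfg.v_G <= cfg.v_D < cfg.v_T):
            raise ConfigError("speed-ordering violation: need v_G <= v_D < v_T")
    elif not (cfg.v_G < cfg.v_D < cfg.v_T):
        raise ConfigError("speed-ordering violation: need v_G < v_D < v_T")
    if not 0.0 <= cfg.initial_gcs_fraction <= 1.0:
        raise bad("initial_gcs_fraction must be in [0, 1]")
    if cfg.model is Model.A_DCS and cfg.initial_gcs_fraction != 0.0:
        raise bad("model A_DCS requires initial_gcs_fraction = 0")
    if cfg.model is Model.A_GCS and cfg.initial_gcs_fraction != 1.0:
        raise bad("model A_GCS requires initial_gcs_fraction = 1")
    if not cfg.eps_capture > 0:
        raise bad("eps_capture must be > 0")
    if cfg.max_placement_attempts < 1:
        raise bad("max_placement_attempts must be >= 1")
    return cfg


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def uniform_point_in_disk(rng: np.random.Generator, R: float) -> np.ndarray:
    """Draw a point uniformly by area from the closed disk of radius ``R``.

    Uses the inverse-CDF radius ``R*sqrt(u)`` so that E|r|^2 = R^2/2.
    Consumes exactly two uniforms (radius then angle) — the fixed draw
    order is part of the reproducibility contract shared with the
    compiled kernel.
    """
    r = R * math.sqrt(rng.random())
    theta = 2.0 * math.pi * rng.random()
    return np.array([r * math.cos(theta), r * math.sin(theta)])


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random direction; consumes exactly one uniform."""
    theta = 2.0 * math.pi * rng.random()
    return np.array([math.cos(theta), math.sin(theta)])


def clamp_to_disk(p: np.ndarray, R: float) -> np.ndarray:
    """Project ``p`` radially onto the disk of radius ``R`` if outside.

    The norm is spelled ``sqrt(x*x + y*y)`` to stay bit-identical with
    the compiled kernel.
    """
    x, y = float(p[0]), float(p[1])
    n = math.sqrt(x * x + y * y)
    if n <= R:
        return p
    return p * (R / n)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class ChaserState:
    """View of one chaser: position, strategy, hunt/rest mode and the two
    spell timers (exactly the timer matching ``mode`` accumulates)."""

    id: int
    pos: np.ndarray
    strategy: Strategy
    mode: Mode
    t_hunt: float = 0.0
    t_rest: float = 0.0


@dataclass
class TargetState:
    id: int
    pos: np.ndarray


@dataclass
class WorldState:
    """Complete simulation state at time ``t``.

    Positions and per-chaser attributes are stored as flat NumPy arrays
    (``chaser_pos`` is (N_C, 2), ``target_pos`` is (N_T, 2)); ``rng`` is
    the single seeded stream that drives every stochastic choice of the
    run.  ``chasers()``/``targets()`` expose the per-agent dataclass view.
    """

    t: float
    chaser_pos: np.ndarray
    chaser_strategy: np.ndarray  # int8, Strategy values
    chaser_mode: np.ndarray      # int8, Mode values
    t_hunt: np.ndarray
    t_rest: np.ndarray
    target_pos: np.ndarray
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def n_chasers(self) -> int:
        return self.chaser_pos.shape[0]

    @property
    def n_targets(self) -> int:
        return self.target_pos.shape[0]

    @property
    def n_gcs(self) -> int:
        return int(np.sum(self.chaser_strategy == Strategy.GCS))

    def chaser(self, i: int) -> ChaserState:
        return ChaserState(
            id=i,
            pos=self.chaser_pos[i],
            strategy=Strategy(int(self.chaser_strategy[i])),
            mode=Mode(int(self.chaser_mode[i])),
            t_hunt=float(self.t_hunt[i]),
            t_rest=float(self.t_rest[i]),
        )

    def target(self, j: int) -> TargetState:
        return TargetState(id=j, pos=self.target_pos[j])

    def chasers(self) -> Iterator[ChaserState]:
        return (self.chaser(i) for i in range(self.n_chasers))

    def targets(self) -> Iterator[TargetState]:
        return (self.target(j) for j in range(self.n_targets))

    def copy(self) -> "WorldState":
        """Deep copy of the arrays; the RNG object is shared (a run owns
        one stream)."""
        return WorldState(
            t=self.t,
            chaser_pos=self.chaser_pos.copy(),
            chaser_strategy=self.chaser_strategy.copy(),
            chaser_mode=self.chaser_mode.copy(),
            t_hunt=self.t_hunt.copy(),
            t_rest=self.t_rest.copy(),
            target_pos=self.target_pos.copy(),
            rng=self.rng,
        )


@dataclass(frozen=True)
class PursuitContext:
    """Per-chaser encirclement context.

    ``gamma`` holds the ids of all other chasers at least as close to the
    focal chaser's nearest target as the focal chaser itself; ``aim`` is
    the point the chaser steers toward, (n+1)*r_T - sum of gamma positions,
    so that reaching it would put the target at the group centroid.
    """

    chaser_id: int
    target_id: int
    d: float
    gamma: tuple[int, ...]
    n: int
    aim: np.ndarray


@dataclass(frozen=True)
class CaptureEvent:
    """One capture: who caught what, where, when, and the (n_G, n_D)
    composition of the pursuing set at the start of the step."""

    t: float
    chaser_id: int
    chaser_strategy: Strategy
    target_id: int
    pos: np.ndarray
    n_G: int
    n_D: int
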