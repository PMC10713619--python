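"""Measured quantities: hunting performance, set statistics, fitness,
equilibrium analysis, and fixation.

The central statistic is the *set-resolved fitness*.  A "set" is the group
of hunting chasers currently pursuing the same target, classified by its
composition (n_G, n_D) = (number of group-strategy chasers, number of
direct-strategy chasers).  With ``N(n_G, n_D)`` set observations counted
every time step over a steady-state window, ``H_G`` / ``H_D`` the captures
scored by each strategy in that class, and the grand totals ``H_total``
and ``N_C_total``, the fitness of a strategy in a class is its share of
captures divided by its share of chaser observations::

    f_G(n_G, n_D) = (H_G / H_total) / (n_G N / N_C_total)
    f_D(n_G, n_D) = (H_D / H_total) / (n_D N / N_C_total)

so f = 1 everywhere when all chasers have equal hunting ability, and the
weighted average of all defined fitnesses is exactly 1 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CaptureEvent, Mode, Strategy, WorldState
from .kinematics import nearest_target_index

__all__ = [
    "SetSnapshot",
    "identify_sets",
    "FitnessCounts",
    "FitnessTable",
    "accumulate_class_counts",
    "compute_fitness_table",
    "NashAnalysis",
    "nash_arrows",
    "hunting_performance",
    "stratified_performance",
    "ensemble_performance",
    "ensemble_stratified_performance",
    "steady_state_mean",
    "ensemble_steady_state",
    "detect_fixation",
    "FixationSummary",
    "fixation_probability",
]


# ---------------------------------------------------------------------------
# sets
# ---------------------------------------------------------------------------

@dataclass
class SetSnapshot:
    """Pursuing-set decomposition at one instant: ``assignment`` maps each
    pursued target id to the (chaser_id, strategy) pairs of the hunting
    chasers whose nearest target it is.  Resting chasers appear nowhere;
    unpursued targets are absent."""

    t: float
    assignment: dict[int, list[tuple[int, Strategy]]]

    def class_key(self, target_id: int) -> tuple[int, int]:
        members = self.assignment.get(target_id, [])
        n_g = sum(1 for _, s in members if s == Strategy.GCS)
        return n_g, len(members) - n_g

    def class_keys(self) -> list[tuple[int, int]]:
        return [self.class_key(tid) for tid in self.assignment]


def identify_sets(world: WorldState,
                  include_resting: bool = False) -> SetSnapshot:
    """Group every hunting chaser with its nearest target (lowest-id
    tie-break, identical to the movement rule)."""
    assignment: dict[int, list[tuple[int, Strategy]]] = {}
    for i in range(world.n_chasers):
        if world.chaser_mode[i] != Mode.HUNT and not include_resting:
            continue
        k = nearest_target_index(world.chaser_pos[i], world)
        assignment.setdefault(k, []).append(
            (i, Strategy(int(world.chaser_strategy[i]))))
    return SetSnapshot(t=world.t, assignment=assignment)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

@dataclass
class FitnessCounts:
    """Raw accumulations on the (n_G, n_D) grid: ``N[g, d]`` set
    observations, ``H_G[g, d]`` / ``H_D[g, d]`` captures."""

    N: np.ndarray
    H_G: np.ndarray
    H_D: np.ndarray

    @property
    def H_total(self) -> int:
        return int(self.H_G.sum() + self.H_D.sum())

    @property
    def N_C_total(self) -> int:
        g = np.arange(self.N.shape[0])[:, None]
        d = np.arange(self.N.shape[1])[None, :]
        return int(((g + d) * self.N).sum())


def accumulate_class_counts(
    snapshots: Iterable[SetSnapshot],
    events: Iterable[CaptureEvent],
    window: tuple[float, float],
    grid_size: int = 101,
) -> FitnessCounts:
    """Accumulate set-class observations and capture counts over a
    steady-state window (both filtered by the same closed interval)."""
    N = np.zeros((grid_size, grid_size), dtype=np.int64)
    H_G = np.zeros_like(N)
    H_D = np.zeros_like(N)
    lo, hi = window
    for snap in snapshots:
        if lo <= snap.t <= hi:
            for g, d in snap.class_keys():
                if g + d >= 1:
                    N[g, d] += 1
    for ev in events:
        if lo <= ev.t <= hi:
            if ev.chaser_strategy == Strategy.GCS:
                H_G[ev.n_G, ev.n_D] += 1
            else:
                H_D[ev.n_G, ev.n_D] += 1
    return FitnessCounts(N=N, H_G=H_G, H_D=H_D)


@dataclass
class FitnessTable:
    """Set-resolved fitness surface.  ``f_G[g, d]`` / ``f_D[g, d]`` are
    NaN where the strategy has no members in the class (never 0 or 1)."""

    counts: FitnessCounts
    f_G: np.ndarray
    f_D: np.ndarray
    H_total: int
    N_C_total: int

    def identity_residual(self) -> float:
        """| (1/N_C_total) * sum[N_G f_G + N_D f_D] - 1 | — zero up to
        float error for any accumulated table (pure algebra)."""
        g = np.arange(self.f_G.shape[0])[:, None]
        d = np.arange(self.f_G.shape[1])[None, :]
        N = self.counts.N
        term_g = np.where(np.isnan(self.f_G), 0.0, g * N * self.f_G)
        term_d = np.where(np.isnan(self.f_D), 0.0, d * N * self.f_D)
        return abs((term_g.sum() + term_d.sum()) / self.N_C_total - 1.0)

    def to_frame(self, max_n: Optional[int] = None) -> pd.DataFrame:
        """Long-format table ``n_G, n_D, N, H_G, H_D, f_G, f_D`` over the
        observed (or capped) grid."""
        rows = []
        side = self.f_G.shape[0]
        hi = side if max_n is None else min(side, max_n + 1)
        for g in range(hi):
            for d in range(hi):
                if g + d < 1 or self.counts.N[g, d] == 0:
                    continue
                rows.append((g, d, self.counts.N[g, d],
                             self.counts.H_G[g, d], self.counts.H_D[g, d],
                             self.f_G[g, d], self.f_D[g, d]))
        return pd.DataFrame(
            rows, columns=["n_G", "n_D", "N", "H_G", "H_D", "f_G", "f_D"])


def compute_fitness_table(
    counts: FitnessCounts | tuple[np.ndarray, np.ndarray, np.ndarray],
) -> FitnessTable:
    """Turn raw class counts into the fitness surface.

    Raises ``ValueError`` when no capture was recorded (H_total = 0: the
    fitness is undefined everywhere).
    """
    if not isinstance(counts, FitnessCounts):
        counts = FitnessCounts(*counts)
    H_total = counts.H_total
    if H_total == 0:
        raise ValueError("H_total = 0: no captures in the window, "
                         "fitness undefined")
    N_C_total = counts.N_C_total
    g = np.arange(counts.N.shape[0])[:, None].astype(float)
    d = np.arange(counts.N.shape[1])[None, :].astype(float)
    N_G = g * counts.N
    N_D = d * counts.N
    with np.errstate(divide="ignore", invalid="ignore"):
        f_G = np.where(N_G > 0,
                       (counts.H_G / H_total) / (N_G / N_C_total), np.nan)
        f_D = np.where(N_D > 0,
                       (counts.H_D / H_total) / (N_D / N_C_total), np.nan)
    return FitnessTable(counts=counts, f_G=f_G, f_D=f_D,
                        H_total=H_total, N_C_total=N_C_total)


# ---------------------------------------------------------------------------
# equilibrium analysis
# ---------------------------------------------------------------------------

@dataclass
class NashAnalysis:
    """Unilateral-switch analysis on the (n_G, n_D) grid.

    ``arrows`` lists the profitable switches: ``(n_G, n_D, "G2D")`` when a
    group chaser in that class would gain by defecting (its fitness in
    (n_G, n_D) is below the direct-strategy fitness in (n_G-1, n_D+1)),
    and ``"D2G"`` symmetrically.  ``equilibria`` are the cells none of
    whose occupants can gain, with every relevant comparison defined;
    ``skipped`` are the comparisons that involved an undefined fitness.
    """

    arrows: list[tuple[int, int, str]]
    equilibria: list[tuple[int, int]]
    skipped: list[tuple[int, int, str]] = field(default_factory=list)


def nash_arrows(table: FitnessTable, max_n: int = 9) -> NashAnalysis:
    f_G, f_D = table.f_G, table.f_D
    arrows: list[tuple[int, int, str]] = []
    skipped: list[tuple[int, int, str]] = []
    equilibria: list[tuple[int, int]] = []
    side = f_G.shape[0]

    def defined(x: float) -> bool:
        return not math.isnan(x)

    for g in range(max_n + 1):
        for d in range(max_n + 1):
            if g + d < 1:
                continue
            stable = True
            occupied = False
            if g >= 1:
                occupied = True
                if g - 1 < side and d + 1 < side and \
                        defined(f_G[g, d]) and defined(f_D[g - 1, d + 1]):
                    if f_G[g, d] < f_D[g - 1, d + 1]:
                        arrows.append((g, d, "G2D"))
                        stable = False
                else:
                    skipped.append((g, d, "G2D"))
                    stable = False  # undetermined, not an equilibrium
            if d >= 1:
                occupied = True
                if g + 1 < side and d - 1 >= 0 and \
                        defined(f_D[g, d]) and defined(f_G[g + 1, d - 1]):
                    if f_D[g, d] < f_G[g + 1, d - 1]:
                        arrows.append((g, d, "D2G"))
                        stable = False
                else:
                    skipped.append((g, d, "D2G"))
                    stable = False
            if occupied and stable:
                equilibria.append((g, d))
    return NashAnalysis(arrows=arrows, equilibria=equilibria,
                        skipped=skipped)


# ---------------------------------------------------------------------------
# hunting performance h(t)
# ---------------------------------------------------------------------------

def hunting_performance(
    captures: pd.DataFrame,
    n_chasers: int,
    bin_width: float = 2e4,
    t_max: Optional[float] = None,
) -> pd.DataFrame:
    """Population hunting performance: captures per chaser in
    non-overlapping windows of width ``bin_width`` centred on
    t = bin_width/2, 3 bin_width/2, ...  Returns columns ``t`` and ``h``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if t_max is None:
        t_max = float(captures["t"].max()) + bin_width if len(captures) \
            else bin_width
    n_bins = max(1, int(math.ceil(t_max / bin_width)))
    idx = np.minimum((captures["t"].to_numpy() / bin_width).astype(int),
                     n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return pd.DataFrame({"t": centers, "h": counts / n_chasers})


def stratified_performance(result) -> pd.DataFrame:
    """Per-strategy, per-category hunting performance of one mixed run.

    For strategy s in category c (heterogeneous = mixed-composition sets,
    homogeneous = single-strategy sets), h is the number of captures
    scored by s-chasers in c-sets during the bin, divided by the
    time-averaged number of s-chasers in c-sets over the bin.  Bins whose
    denominator is zero yield NaN (undefined, not zero).

    Returns columns ``t, strategy, category, h``.
    """
    occ = result.occupancy
    steps = result.occupancy_steps
    n_bins = len(steps)
    caps = result.captures
    het = (caps["n_G"] >= 1) & (caps["n_D"] >= 1)
    is_g = caps["strategy"] == int(Strategy.GCS)
    bin_idx = np.minimum((caps["t"].to_numpy() / result.bin_width)
                         .astype(int), n_bins - 1)

    frames = []
    centers = (np.arange(n_bins) + 0.5) * result.bin_width
    selections = [
        ("GCS", "heterogeneous", is_g & het, 0),
        ("DCS", "heterogeneous", ~is_g & het, 1),
        ("GCS", "homogeneous", is_g & ~het, 2),
        ("DCS", "homogeneous", ~is_g & ~het, 3),
    ]
    for name, cat, mask, col in selections:
        counts = np.bincount(bin_idx[mask.to_numpy()], minlength=n_bins)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.where(steps > 0, occ[:, col] / np.maximum(steps, 1),
                             np.nan)
            h = np.where(denom > 0, counts / denom, np.nan)
        frames.append(pd.DataFrame(
            {"t": centers, "strategy": name, "category": cat, "h": h}))
    return pd.concat(frames, ignore_index=True)


def ensemble_performance(ens, bin_width: Optional[float] = None
                         ) -> pd.DataFrame:
    """Ensemble-mean population h(t): mean over runs of the per-run
    series, with the between-run standard error."""
    per_run = []
    for r in ens.runs:
        bw = bin_width or r.bin_width
        df = hunting_performance(r.captures, r.config.N_C, bw,
                                 r.n_steps * r.config.delta_t)
        per_run.append(df["h"].to_numpy())
    t = hunting_performance(ens.runs[0].captures, ens.runs[0].config.N_C,
                            bin_width or ens.runs[0].bin_width,
                            ens.runs[0].n_steps
                            * ens.runs[0].config.delta_t)["t"]
    H = np.vstack(per_run)
    se = H.std(axis=0, ddof=1) / math.sqrt(len(per_run)) if len(per_run) > 1 \
        else np.zeros(H.shape[1])
    return pd.DataFrame({"t": t, "h": H.mean(axis=0), "se": se})


def ensemble_stratified_performance(ens) -> pd.DataFrame:
    """Pooled stratified h(t) over an ensemble: summed capture counts
    divided by summed time-averaged occupancies (robust to bins where a
    single run has an empty category)."""
    n_bins = len(ens.runs[0].occupancy_steps)
    bw = ens.runs[0].bin_width
    centers = (np.arange(n_bins) + 0.5) * bw
    cap_tot = np.zeros((n_bins, 4))
    occ_tot = np.zeros((n_bins, 4))
    for r in ens.runs:
        caps = r.captures
        het = (caps["n_G"] >= 1) & (caps["n_D"] >= 1)
        is_g = caps["strategy"] == int(Strategy.GCS)
        bin_idx = np.minimum((caps["t"].to_numpy() / bw).astype(int),
                             n_bins - 1)
        steps = np.maximum(r.occupancy_steps, 1)
        for col, mask in enumerate([is_g & het, ~is_g & het,
                                    is_g & ~het, ~is_g & ~het]):
            cap_tot[:, col] += np.bincount(bin_idx[mask.to_numpy()],
                                           minlength=n_bins)
            occ_tot[:, col] += r.occupancy[:, col] / steps
    frames = []
    labels = [("GCS", "heterogeneous"), ("DCS", "heterogeneous"),
              ("GCS", "homogeneous"), ("DCS", "homogeneous")]
    with np.errstate(divide="ignore", invalid="ignore"):
        for col, (name, cat) in enumerate(labels):
            h = np.where(occ_tot[:, col] > 0,
                         cap_tot[:, col] / occ_tot[:, col], np.nan)
            frames.append(pd.DataFrame(
                {"t": centers, "strategy": name, "category": cat, "h": h}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# steady state and fixation
# ---------------------------------------------------------------------------

def steady_state_mean(t: np.ndarray, y: np.ndarray,
                      window: tuple[float, float]) -> float:
    """Mean of a series restricted to the closed window; raises on an
    empty restriction."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (t >= window[0]) & (t <= window[1]) & ~np.isnan(y)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return float(y[mask].mean())


def ensemble_steady_state(values: Sequence[float]) -> tuple[float, float]:
    """Mean of per-run steady-state values with the between-run standard
    error sd/sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no runs")
    se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), se


def detect_fixation(t: np.ndarray, n_gcs: np.ndarray, n_chasers: int
                    ) -> tuple[str, Optional[float]]:
    """First time the strategy-count series is absorbed at all-GCS or
    all-DCS; ``("none", None)`` if neither happens."""
    n_gcs = np.asarray(n_gcs)
    hit_g = np.nonzero(n_gcs == n_chasers)[0]
    hit_d = np.nonzero(n_gcs == 0)[0]
    i_g = hit_g[0] if hit_g.size else None
    i_d = hit_d[0] if hit_d.size else None
    if i_g is not None and (i_d is None or i_g < i_d):
        return "GCS", float(np.asarray(t)[i_g])
    if i_d is not None:
        return "DCS", float(np.asarray(t)[i_d])
    return "none", None


@dataclass
class FixationSummary:
    """Ensemble fixation statistics: P_fix per strategy with binomial
    standard errors; non-fixed runs count only in the denominator."""

    n_runs: int
    n_gcs_fixations: int
    n_dcs_fixations: int
    n_none: int
    p_fix_gcs: float
    p_fix_dcs: float
    se_gcs: float
    se_dcs: float
    fixation_times_gcs: list[float] = field(default_factory=list)
    fixation_times_dcs: list[float] = field(default_factory=list)


def fixation_probability(
    outcomes: Sequence[str],
    times: Optional[Sequence[Optional[float]]] = None,
) -> FixationSummary:
    n = len(outcomes)
    if n < 1:
        raise ValueError("need at least one run")
    n_g = sum(1 for o in outcomes if o == "GCS")
    n_d = sum(1 for o in outcomes if o == "DCS")
    p_g, p_d = n_g / n, n_d / n
    times = times if times is not None else [None] * n
    return FixationSummary(
        n_runs=n, n_gcs_fixations=n_g, n_dcs_fixations=n_d,
        n_none=n - n_g - n_d, p_fix_gcs=p_g, p_fix_dcs=p_d,
        se_gcs=math.sqrt(p_g * (1 - p_g) / n),
        se_dcs=math.sqrt(p_d * (1 - p_d) / n),
        fixation_times_gcs=[t for o, t in zip(outcomes, times)
                            if o == "GCS" and t is not None],
        fixation_times_dcs=[t for o, t in zip(outcomes, times)
                            if o == "DCS" and t is not None],
    )
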