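"""Compiled fast path of the simulation engine.

``_run_steps`` replays, step for step and draw for draw, the algorithm of
:mod:`groupchase.engine`'s pure-Python reference loop.  Bitwise agreement
of the two engines is a tested contract; it hinges on three conventions
shared with the reference code:

* norms are spelled ``sqrt(x*x + y*y)`` and nearest-entity scans compare
  squared distances;
* every stochastic choice consumes uniforms from the one shared
  ``np.random.Generator`` in a fixed order (mode draws, proposals in
  agent-index order, one Fisher-Yates shuffle per species per step,
  rejection sampling for replacement targets);
* numba's ``Generator.random()`` is bit-compatible with NumPy's and the
  generator state persists across the JIT boundary.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .core import Model, PlacementError, SimulationConfig, WorldState

__all__ = ["run_kernel"]

# error codes returned by the kernel
_OK = 0
_ERR_PLACEMENT = 1
_ERR_CAPACITY = 2

HUNT = 0
REST = 1
GCS = 1


@njit(cache=True)
def _run_steps(rng, n_steps, t0,
               cpos, strat, mode, thunt, trest, tpos,
               R, vT, vD, vG, dt, rmin, rhaz, rlearn, Thunt, Trest,
               eps, max_attempts, learning_on,
               rest_hazard, rest_gamma, rest_sets,
               win_lo, win_hi, bin_width, n_bins,
               occupancy, occ_steps, class_N, class_HG, class_HD,
               cap_t, cap_ch, cap_st, cap_tg, cap_x, cap_y, cap_g, cap_d,
               sample_every, ser_t, ser_n,
               already_fixed, stop_at_fixation):
    NC = cpos.shape[0]
    NT = tpos.shape[0]
    rmin2 = rmin * rmin
    eps2 = eps * eps
    rlearn2 = rlearn * rlearn
    vT_dt = vT * dt
    vD_dt = vD * dt
    vG_dt = vG * dt
    vmax_dt = vD_dt if vD_dt > vG_dt else vG_dt

    dist2 = np.empty((NC, NT))
    nearest = np.empty(NC, dtype=np.int64)
    att_c = np.empty((NC, 2))
    att_t = np.empty((NT, 2))
    set_g = np.zeros(NT, dtype=np.int64)
    set_d = np.zeros(NT, dtype=np.int64)
    perm_c = np.empty(NC, dtype=np.int64)
    perm_t = np.empty(NT, dtype=np.int64)

    # Stamped uniform grid over pre-move positions.  Neighbour queries
    # replace the O(N^2) exclusion/capture scans with a 3x3-cell lookup;
    # the cell size (2.0) far exceeds the largest interaction radius
    # (r_min + 2 steps < 0.36), so the candidate set provably contains
    # every agent the full scan could flag, and the final predicate is
    # evaluated identically -- the committed state is bit-for-bit the
    # same as the reference double loop's.
    cell = 2.0
    gw = int(2.0 * R / cell) + 3
    n_cells = gw * gw
    c_head = np.empty(n_cells, dtype=np.int32)
    c_stamp = np.zeros(n_cells, dtype=np.int64)
    c_next = np.empty(NC, dtype=np.int32)
    t_head = np.empty(n_cells, dtype=np.int32)
    t_stamp = np.zeros(n_cells, dtype=np.int64)
    t_next = np.empty(2 * NT, dtype=np.int32)  # slots NT.. for re-inserts
    t_id = np.empty(2 * NT, dtype=np.int32)
    stamp = 0

    n_caps = 0
    n_ser = 0
    fix_code = -1  # -1 none, 0 DCS, 1 GCS
    fix_time = -1.0
    fixed = already_fixed
    t = t0

    for s in range(n_steps):
        # --- 1. mode draws (index order; one uniform each) -------------
        for i in range(NC):
            u = rng.random()
            if mode[i] == HUNT:
                p = thunt[i] / Thunt
                if p > 1.0:
                    p = 1.0
                if u < p:
                    mode[i] = REST
                    trest[i] = 0.0
            else:
                p = trest[i] / Trest
                if p > 1.0:
                    p = 1.0
                if u < p:
                    mode[i] = HUNT
                    thunt[i] = 0.0
            if mode[i] == HUNT:
                thunt[i] += dt
            else:
                trest[i] += dt

        # --- distances and nearest targets (pre-move positions) --------
        for i in range(NC):
            bx = cpos[i, 0]
            by = cpos[i, 1]
            best = math.inf
            bj = 0
            for j in range(NT):
                dx = tpos[j, 0] - bx
                dy = tpos[j, 1] - by
                d2 = dx * dx + dy * dy
                dist2[i, j] = d2
                if d2 < best:
                    best = d2
                    bj = j
            nearest[i] = bj

        # --- 2. pursuing-set snapshot ----------------------------------
        for j in range(NT):
            set_g[j] = 0
            set_d[j] = 0
        for i in range(NC):
            if mode[i] == HUNT or rest_sets:
                k = nearest[i]
                if strat[i] == GCS:
                    set_g[k] += 1
                else:
                    set_d[k] += 1

        b = int(t / bin_width)
        if b > n_bins - 1:
            b = n_bins - 1
        for j in range(NT):
            g = set_g[j]
            d = set_d[j]
            if g > 0 and d > 0:
                occupancy[b, 0] += g
                occupancy[b, 1] += d
            elif g > 0:
                occupancy[b, 2] += g
            elif d > 0:
                occupancy[b, 3] += d
        occ_steps[b] += 1
        in_window = (t >= win_lo) and (t <= win_hi)
        if in_window:
            for j in range(NT):
                if set_g[j] + set_d[j] >= 1:
                    class_N[set_g[j], set_d[j]] += 1

        # --- 3. chaser proposals (index order) -------------------------
        for i in range(NC):
            speed = vG_dt if strat[i] == GCS else vD_dt
            px = cpos[i, 0]
            py = cpos[i, 1]
            if mode[i] == REST:
                theta = 2.0 * math.pi * rng.random()
                ax = px + speed * math.cos(theta)
                ay = py + speed * math.sin(theta)
            else:
                k = nearest[i]
                d2 = dist2[i, k]
                tx = tpos[k, 0]
                ty = tpos[k, 1]
                if d2 <= speed * speed:
                    ax = tx
                    ay = ty
                elif strat[i] == GCS:
                    aimx = tx
                    aimy = ty
                    for j in range(NC):
                        if j == i:
                            continue
                        if (not rest_gamma) and mode[j] != HUNT:
                            continue
                        if dist2[j, k] <= d2:
                            aimx += tx - cpos[j, 0]
                            aimy += ty - cpos[j, 1]
                    vx = aimx - px
                    vy = aimy - py
                    n = math.sqrt(vx * vx + vy * vy)
                    if n == 0.0:
                        theta = 2.0 * math.pi * rng.random()
                        ax = px + speed * math.cos(theta)
                        ay = py + speed * math.sin(theta)
                    else:
                        ax = px + speed * (vx / n)
                        ay = py + speed * (vy / n)
                else:
                    dx = tx - px
                    dy = ty - py
                    n = math.sqrt(dx * dx + dy * dy)
                    ax = px + speed * (dx / n)
                    ay = py + speed * (dy / n)
            # clamp to disk
            n = math.sqrt(ax * ax + ay * ay)
            if n > R:
                scale = R / n
                ax = ax * scale
                ay = ay * scale
            att_c[i, 0] = ax
            att_c[i, 1] = ay

        # --- 4. target proposals (index order) -------------------------
        for j in range(NT):
            px = tpos[j, 0]
            py = tpos[j, 1]
            # nearest chaser hazard; reuses the pre-move distance matrix
            # ((a-b)^2 == (b-a)^2 bitwise, so the scan is FP-identical to
            # a fresh computation)
            best = math.inf
            bi = -1
            for i in range(NC):
                if (not rest_hazard) and mode[i] != HUNT:
                    continue
                d2 = dist2[i, j]
                if d2 < best:
                    best = d2
                    bi = i
            hx = 0.0
            hy = 0.0
            have = False
            best_d = math.inf
            if bi >= 0:
                best_d = math.sqrt(best)
                hx = cpos[bi, 0]
                hy = cpos[bi, 1]
                have = True
            rt = math.sqrt(px * px + py * py)
            if rt > 0.0:
                d_boundary = R - rt
                if d_boundary < best_d:  # boundary loses ties
                    best_d = d_boundary
                    scale = R / rt
                    hx = px * scale
                    hy = py * scale
                    have = True
            if (not have) or best_d > rhaz:
                theta = 2.0 * math.pi * rng.random()
                dirx = math.cos(theta)
                diry = math.sin(theta)
            else:
                awayx = px - hx
                awayy = py - hy
                n = math.sqrt(awayx * awayx + awayy * awayy)
                if n == 0.0:
                    theta = 2.0 * math.pi * rng.random()
                    dirx = math.cos(theta)
                    diry = math.sin(theta)
                else:
                    dirx = awayx / n
                    diry = awayy / n
            ax = px + vT_dt * dirx
            ay = py + vT_dt * diry
            n = math.sqrt(ax * ax + ay * ay)
            if n > R:
                scale = R / n
                ax = ax * scale
                ay = ay * scale
            att_t[j, 0] = ax
            att_t[j, 1] = ay

        # --- 5. commit chasers (random order, same-species exclusion) --
        # pre-move chaser grid; moved chasers drift < one step from their
        # registered cell, well inside the 3x3 search margin
        stamp += 1
        for i in range(NC):
            gx = int((cpos[i, 0] + R) / cell) + 1
            gy = int((cpos[i, 1] + R) / cell) + 1
            c = gx * gw + gy
            if c_stamp[c] != stamp:
                c_stamp[c] = stamp
                c_head[c] = -1
            c_next[i] = c_head[c]
            c_head[c] = i
        for i in range(NC):
            perm_c[i] = i
        for i in range(NC - 1, 0, -1):
            jj = int(rng.random() * (i + 1))
            tmp = perm_c[i]
            perm_c[i] = perm_c[jj]
            perm_c[jj] = tmp
        for q in range(NC):
            idx = perm_c[q]
            ax = att_c[idx, 0]
            ay = att_c[idx, 1]
            gx = int((ax + R) / cell) + 1
            gy = int((ay + R) / cell) + 1
            blocked = False
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    c = (gx + ox) * gw + (gy + oy)
                    if c_stamp[c] != stamp:
                        continue
                    m = c_head[c]
                    while m >= 0:
                        if m != idx:
                            dx = ax - cpos[m, 0]
                            dy = ay - cpos[m, 1]
                            if dx * dx + dy * dy < rmin2:
                                blocked = True
                                break
                        m = c_next[m]
                    if blocked:
                        break
                if blocked:
                    break
            if not blocked:
                cpos[idx, 0] = ax
                cpos[idx, 1] = ay

        # --- 6. commit targets: captures, replacement, moves -----------
        # pre-move target grid (replacement targets are re-inserted at
        # their new cell so later movers still see them)
        stamp += 1
        for j in range(NT):
            gx = int((tpos[j, 0] + R) / cell) + 1
            gy = int((tpos[j, 1] + R) / cell) + 1
            c = gx * gw + gy
            if t_stamp[c] != stamp:
                t_stamp[c] = stamp
                t_head[c] = -1
            t_next[j] = t_head[c]
            t_head[c] = j
            t_id[j] = j
        n_slots = NT
        for j in range(NT):
            perm_t[j] = j
        for j in range(NT - 1, 0, -1):
            jj = int(rng.random() * (j + 1))
            tmp = perm_t[j]
            perm_t[j] = perm_t[jj]
            perm_t[jj] = tmp
        step_cap_start = n_caps
        for q in range(NT):
            j = perm_t[q]
            px = tpos[j, 0]
            py = tpos[j, 1]
            # capture scan over grid candidates; lexicographic (d2, id)
            # minimum reproduces the ascending-id strict-< reference scan
            best = math.inf
            bi = -1
            gx = int((px + R) / cell) + 1
            gy = int((py + R) / cell) + 1
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    c = (gx + ox) * gw + (gy + oy)
                    if c_stamp[c] != stamp - 1:
                        continue
                    i = c_head[c]
                    while i >= 0:
                        if mode[i] == HUNT:
                            dx = cpos[i, 0] - px
                            dy = cpos[i, 1] - py
                            d2 = dx * dx + dy * dy
                            if d2 <= eps2 and (d2 < best or
                                               (d2 == best and i < bi)):
                                best = d2
                                bi = i
                        i = c_next[i]
            if bi >= 0:
                # capture
                if n_caps >= cap_t.shape[0]:
                    return (n_caps, n_ser, fix_code, fix_time, t,
                            _ERR_CAPACITY)
                cap_t[n_caps] = t
                cap_ch[n_caps] = bi
                cap_st[n_caps] = strat[bi]
                cap_tg[n_caps] = j
                cap_x[n_caps] = px
                cap_y[n_caps] = py
                cap_g[n_caps] = set_g[j]
                cap_d[n_caps] = set_d[j]
                if in_window:
                    if strat[bi] == GCS:
                        class_HG[set_g[j], set_d[j]] += 1
                    else:
                        class_HD[set_g[j], set_d[j]] += 1
                n_caps += 1
                # replacement: uniform disk point >= r_min from every agent
                placed = False
                for _ in range(max_attempts):
                    r = R * math.sqrt(rng.random())
                    theta = 2.0 * math.pi * rng.random()
                    qx = r * math.cos(theta)
                    qy = r * math.sin(theta)
                    ok = True
                    for m in range(NC):
                        dx = qx - cpos[m, 0]
                        dy = qy - cpos[m, 1]
                        if dx * dx + dy * dy < rmin2:
                            ok = False
                            break
                    if ok:
                        for m in range(NT):
                            if m == j:
                                continue
                            dx = qx - tpos[m, 0]
                            dy = qy - tpos[m, 1]
                            if dx * dx + dy * dy < rmin2:
                                ok = False
                                break
                    if ok:
                        tpos[j, 0] = qx
                        tpos[j, 1] = qy
                        placed = True
                        break
                if not placed:
                    return (n_caps, n_ser, fix_code, fix_time, t,
                            _ERR_PLACEMENT)
                # register the replacement at its new cell so later
                # movers in this sweep still see it
                gx = int((tpos[j, 0] + R) / cell) + 1
                gy = int((tpos[j, 1] + R) / cell) + 1
                c = gx * gw + gy
                if t_stamp[c] != stamp:
                    t_stamp[c] = stamp
                    t_head[c] = -1
                t_next[n_slots] = t_head[c]
                t_head[c] = n_slots
                t_id[n_slots] = j
                n_slots += 1
            else:
                ax = att_t[j, 0]
                ay = att_t[j, 1]
                gx = int((ax + R) / cell) + 1
                gy = int((ay + R) / cell) + 1
                blocked = False
                for ox in range(-1, 2):
                    for oy in range(-1, 2):
                        c = (gx + ox) * gw + (gy + oy)
                        if t_stamp[c] != stamp:
                            continue
                        s_ = t_head[c]
                        while s_ >= 0:
                            m = t_id[s_]
                            if m != j:
                                dx = ax - tpos[m, 0]
                                dy = ay - tpos[m, 1]
                                if dx * dx + dy * dy < rmin2:
                                    blocked = True
                                    break
                            s_ = t_next[s_]
                        if blocked:
                            break
                    if blocked:
                        break
                if not blocked:
                    tpos[j, 0] = ax
                    tpos[j, 1] = ay

        # --- 7. learning (imitation of successful capturers) -----------
        if learning_on:
            for e in range(step_cap_start, n_caps):
                snew = strat[cap_ch[e]]
                ex = cap_x[e]
                ey = cap_y[e]
                for i in range(NC):
                    dx = cpos[i, 0] - ex
                    dy = cpos[i, 1] - ey
                    if dx * dx + dy * dy <= rlearn2:
                        strat[i] = snew

        # --- 8. advance time, record series / fixation -----------------
        t = t + dt
        if not fixed:
            ng = 0
            for i in range(NC):
                if strat[i] == GCS:
                    ng += 1
            if ng == NC:
                fix_code = 1
                fix_time = t
                fixed = True
            elif ng == 0:
                fix_code = 0
                fix_time = t
                fixed = True
        if (s + 1) % sample_every == 0:
            ng = 0
            for i in range(NC):
                if strat[i] == GCS:
                    ng += 1
            ser_t[n_ser] = t
            ser_n[n_ser] = ng
            n_ser += 1
        if stop_at_fixation and fixed:
            break

    return (n_caps, n_ser, fix_code, fix_time, t, _OK)


def run_kernel(world: WorldState, cfg: SimulationConfig, n_steps: int,
               window: tuple[float, float], bin_width: float,
               sample_every: int, keep_final_world: bool,
               stop_at_fixation: bool = False):
    """Drive the compiled kernel on an initialized world and assemble a
    :class:`groupchase.engine.RunResult`."""
    from .engine import RunResult, _check_fixation, captures_frame

    n_bins = max(1, int(math.ceil(n_steps * cfg.delta_t / bin_width)))
    side = cfg.N_C + 1
    occupancy = np.zeros((n_bins, 4))
    occ_steps = np.zeros(n_bins, dtype=np.int64)
    class_N = np.zeros((side, side), dtype=np.int64)
    class_HG = np.zeros((side, side), dtype=np.int64)
    class_HD = np.zeros((side, side), dtype=np.int64)

    # generous margin over the observed ~0.012 captures/step at the
    # published densities; overflow aborts with a clear error
    capacity = int(0.08 * n_steps * max(1.0, cfg.N_C / 100.0)) + 4096
    cap_t = np.empty(capacity)
    cap_ch = np.empty(capacity, dtype=np.int32)
    cap_st = np.empty(capacity, dtype=np.int8)
    cap_tg = np.empty(capacity, dtype=np.int32)
    cap_x = np.empty(capacity)
    cap_y = np.empty(capacity)
    cap_g = np.empty(capacity, dtype=np.int32)
    cap_d = np.empty(capacity, dtype=np.int32)

    n_samples = n_steps // sample_every + 2
    ser_t = np.empty(n_samples)
    ser_n = np.empty(n_samples, dtype=np.int64)

    n_gcs0 = world.n_gcs
    fix_outcome, fix_time = _check_fixation(n_gcs0, cfg.N_C, 0.0)
    learning_on = cfg.model is Model.C
    if stop_at_fixation and fix_outcome != "none":
        n_steps = 0

    (n_caps, n_ser, fix_code, k_fix_time, t_end, err) = _run_steps(
        world.rng, n_steps, world.t,
        world.chaser_pos, world.chaser_strategy, world.chaser_mode,
        world.t_hunt, world.t_rest, world.target_pos,
        cfg.R, cfg.v_T, cfg.v_D, cfg.v_G, cfg.delta_t, cfg.r_min,
        cfg.r_haz, cfg.r_learn, cfg.T_hunt, cfg.T_rest,
        cfg.eps_capture, cfg.max_placement_attempts, learning_on,
        cfg.resting_chasers_are_hazards, cfg.resting_chasers_in_gamma,
        cfg.resting_chasers_in_sets,
        window[0], window[1], bin_width, n_bins,
        occupancy, occ_steps, class_N, class_HG, class_HD,
        cap_t, cap_ch, cap_st, cap_tg, cap_x, cap_y, cap_g, cap_d,
        sample_every, ser_t, ser_n,
        fix_outcome != "none", stop_at_fixation)
    if err == _ERR_PLACEMENT:
        raise PlacementError(
            f"placement failure after {cfg.max_placement_attempts} attempts "
            f"at t={t_end}")
    if err == _ERR_CAPACITY:
        raise RuntimeError(
            "capture buffer overflow — capture rate far above the expected "
            "regime; this configuration needs a larger buffer")
    world.t = t_end

    if fix_outcome == "none" and fix_code >= 0:
        fix_outcome = "GCS" if fix_code == 1 else "DCS"
        fix_time = k_fix_time

    captures = captures_frame({
        "t": cap_t[:n_caps],
        "chaser_id": cap_ch[:n_caps],
        "strategy": cap_st[:n_caps],
        "target_id": cap_tg[:n_caps],
        "x": cap_x[:n_caps],
        "y": cap_y[:n_caps],
        "n_G": cap_g[:n_caps],
        "n_D": cap_d[:n_caps],
    })

    series_t = np.concatenate(([0.0], ser_t[:n_ser]))
    series_n = np.concatenate(([n_gcs0], ser_n[:n_ser]))
    if series_t[-1] != world.t:
        series_t = np.append(series_t, world.t)
        series_n = np.append(series_n, world.n_gcs)

    return RunResult(
        config=cfg, seed=cfg.seed, n_steps=n_steps, captures=captures,
        series_t=series_t, series_n_gcs=series_n,
        class_N=class_N, class_HG=class_HG, class_HD=class_HD,
        window=window, bin_width=bin_width, occupancy=occupancy,
        occupancy_steps=occ_steps, fixation_outcome=fix_outcome,
        fixation_time=fix_time,
        final_world=world if keep_final_world else None,
    )
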