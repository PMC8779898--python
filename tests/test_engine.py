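"""Reference engine: pair forces, bonded terms, cell list, integration,
schedule handling and the counter-based pair RNG."""

import numpy as np
import pytest

from dpdmem import _kernels
from dpdmem.engine import (
    ReferenceEngine,
    RunParams,
    Schedule,
    ScheduleEvent,
    SimulationBox,
    SystemState,
    neighbor_pairs,
    pair_rng,
)
from dpdmem.model import BEADS, EpsilonSpec, InteractionTable

from conftest import brute_force_pairs, random_state, two_bead_state


def make_engine(state, table=None, seed=7, strict=False, schedule=None):
    table = table or EpsilonSpec().make_table()
    return ReferenceEngine(state, table, RunParams(seed=seed), schedule, strict_order=strict)


def conservative_only_table():
    """Thermostat switched off: gamma = 0 implies sigma = 0."""
    return InteractionTable(gamma=0.0)


class TestPairwiseForces:
    def test_zero_at_cutoff(self, small_box):
        state = two_bead_state(small_box, 1.0)
        eng = make_engine(state, conservative_only_table())
        f = eng.compute_forces(state.vel, 0)
        assert np.allclose(f, 0.0)

    def test_conservative_magnitude_at_half_cutoff(self, small_box):
        # a_WW (1 - r) = 25 * 0.5 = 12.5 along the pair axis
        state = two_bead_state(small_box, 0.5)
        eng = make_engine(state, conservative_only_table())
        f = eng.compute_forces(state.vel, 0)
        assert f[0, 0] == pytest.approx(-12.5, abs=1e-12)
        assert f[1, 0] == pytest.approx(12.5, abs=1e-12)
        assert np.allclose(f[:, 1:], 0.0)

    def test_newtons_third_law_with_thermostat(self, rng):
        state = random_state(rng, 200)
        state.vel = rng.normal(size=(200, 3))
        eng = make_engine(state)
        f = eng.compute_forces(state.vel, 3)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_overlapping_beads_finite(self, small_box):
        state = two_bead_state(small_box, 0.0)
        eng = make_engine(state)
        f = eng.compute_forces(state.vel, 0)
        assert np.isfinite(f).all()
        assert np.allclose(f, 0.0)  # direction undefined -> no pair force

    def test_cutoff_locality_under_box_doubling(self, rng):
        # identical bead content far from the boundary: forces identical
        pos = 2.0 + rng.uniform(0, 2, (40, 3))
        vel = rng.normal(size=(40, 3))
        forces = []
        for L in (6.0, 12.0):
            state = SystemState(SimulationBox((L, L, L)), pos.copy())
            state.vel = vel.copy()
            eng = make_engine(state, strict=True)
            forces.append(eng.compute_forces(state.vel, 5))
        assert np.array_equal(forces[0], forces[1])


class TestBondForces:
    def test_rest_length_zero_force(self, small_box):
        state = two_bead_state(small_box, 0.5)
        state.bonds = np.array([[0, 1]])
        state.bond_params = np.array([[128.0, 0.5]])
        f = np.zeros((2, 3))
        _kernels.bond_forces(state.pos, state.bonds, state.bond_params, small_box.array, f)
        assert np.allclose(f, 0.0)

    def test_stretched_bond_magnitude(self, small_box):
        state = two_bead_state(small_box, 1.0)
        f = np.zeros((2, 3))
        e = _kernels.bond_forces(
            state.pos, np.array([[0, 1]]), np.array([[128.0, 0.5]]), small_box.array, f
        )
        # |F| = k (r - l0) = 128 * 0.5 = 64, pulling the beads together
        assert f[0, 0] == pytest.approx(64.0)
        assert f[1, 0] == pytest.approx(-64.0)
        assert e == pytest.approx(0.5 * 128 * 0.25)

    def test_antisymmetry_random(self, rng, small_box):
        state = two_bead_state(small_box, float(rng.uniform(0.1, 1.5)))
        f = np.zeros((2, 3))
        _kernels.bond_forces(
            state.pos, np.array([[0, 1]]), np.array([[128.0, 0.5]]), small_box.array, f
        )
        assert np.allclose(f[0], -f[1])


class TestAngleForces:
    def run_angle(self, coords, k3=5.0, phi0=0.0, box=20.0):
        pos = np.asarray(coords, dtype=np.float64) + box / 2
        f = np.zeros((3, 3))
        e = _kernels.angle_forces(
            pos,
            np.array([[0, 1, 2]]),
            np.array([[k3, phi0]]),
            np.array([box] * 3),
            f,
        )
        return e, f

    def test_straight_triple_is_minimum(self):
        e, f = self.run_angle([[0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]])
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f, 0.0)

    def test_right_angle_energy(self):
        e, f = self.run_angle([[0, 0, 0], [0.5, 0, 0], [0.5, 0.5, 0]], k3=5.0)
        assert e == pytest.approx(5.0)
        assert np.abs(f.sum(axis=0)).max() < 1e-12

    def test_net_force_and_torque_vanish(self, rng):
        for _ in range(20):
            coords = rng.uniform(-1, 1, (3, 3))
            e, f = self.run_angle(coords)
            assert np.abs(f.sum(axis=0)).max() < 1e-10
            torque = np.cross(coords - coords.mean(axis=0), f).sum(axis=0)
            assert np.abs(torque).max() < 1e-10

    def test_gradient_matches_finite_difference(self, rng):
        coords = rng.uniform(-1, 1, (3, 3))
        e0, f = self.run_angle(coords)
        h = 1e-6
        for b in range(3):
            for ax in range(3):
                cp = coords.copy()
                cp[b, ax] += h
                ep, _ = self.run_angle(cp)
                cm = coords.copy()
                cm[b, ax] -= h
                em, _ = self.run_angle(cm)
                assert f[b, ax] == pytest.approx(-(ep - em) / (2 * h), abs=1e-5)


class TestCellList:
    def test_floor_assignment(self):
        box = np.array([3.0, 3.0, 3.0])
        nc = np.array([3, 3, 3], dtype=np.int64)
        cell = _kernels._assign_cells(np.array([[2.5, 0.1, 1.0]]), box, nc)
        assert cell[0] == (2 * 3 + 0) * 3 + 1

    def test_boundary_bead_stays_in_last_cell(self):
        box = np.array([8.0, 8.0, 8.0])
        nc = np.array([8, 8, 8], dtype=np.int64)
        x = 8.0 - 1e-12
        cell = _kernels._assign_cells(np.array([[x, 0.0, 0.0]]), box, nc)
        assert cell[0] == 7 * 64

    @pytest.mark.parametrize("trial", range(5))
    def test_pairs_match_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(50, 400))
        state = random_state(rng, n)
        got = [tuple(p) for p in neighbor_pairs(state)]
        expected = brute_force_pairs(state.pos, state.box.array, 1.0)
        assert got == expected


class TestIntegration:
    def test_free_bead_moves_uniformly(self):
        box = SimulationBox((6.0, 6.0, 6.0))
        state = SystemState(box, np.array([[1.0, 1.0, 1.0]]))
        state.vel = np.array([[0.5, -0.25, 0.1]])
        eng = make_engine(state)
        eng.run(100)
        expected = (np.array([1.0, 1.0, 1.0]) + 100 * 0.02 * state.vel[0]) % 6.0
        assert np.allclose(state.pos[0], expected, atol=1e-12)
        assert np.allclose(state.vel[0], [0.5, -0.25, 0.1])

    def test_momentum_conserved(self, rng):
        state = random_state(rng, 300)
        v = rng.normal(size=(300, 3))
        state.vel = v - v.mean(axis=0)
        eng = make_engine(state)
        eng.run(500)
        assert np.abs(state.total_momentum()).max() < 1e-9

    def test_determinism_same_seed(self, rng):
        states = []
        for _ in range(2):
            r = np.random.default_rng(5)
            st = random_state(r, 150)
            st.vel = r.normal(size=(150, 3))
            eng = make_engine(st, seed=42)
            eng.run(50)
            states.append(st)
        assert np.array_equal(states[0].pos, states[1].pos)
        assert np.array_equal(states[0].vel, states[1].vel)

    def test_nonfinite_detection(self, small_box):
        state = two_bead_state(small_box, 0.5)
        state.pos[0, 0] = np.nan
        eng = make_engine(state)
        with pytest.raises(RuntimeError, match="non-finite"):
            eng.run(1)


class TestSchedule:
    def test_event_applies_before_force_evaluation(self, rng):
        state = random_state(rng, 50)
        table = EpsilonSpec().make_table()
        sched = Schedule([ScheduleEvent(2, ("E", "H_B"), 5.0)])
        eng = make_engine(state, table, schedule=sched)
        eng.run(1)
        assert table.a[BEADS.index("E"), BEADS.index("H_B")] == 25.0
        eng.run(2)
        assert table.a[BEADS.index("E"), BEADS.index("H_B")] == 5.0

    def test_empty_schedule_leaves_table(self, rng):
        state = random_state(rng, 50)
        table = EpsilonSpec().make_table()
        before = table.a.copy()
        make_engine(state, table).run(5)
        assert np.array_equal(table.a, before)

    def test_same_step_events_apply_in_order(self):
        table = EpsilonSpec().make_table()
        sched = Schedule(
            [ScheduleEvent(3, ("E", "E"), 8.0), ScheduleEvent(3, ("E", "E"), 12.0)]
        )
        sched.apply_due(3, table)
        assert table.a[BEADS.index("E"), BEADS.index("E")] == 12.0

    def test_non_variable_pair_rejected_at_load(self):
        with pytest.raises(ValueError):
            ScheduleEvent(0, ("W", "W"), 10.0)

    def test_decreasing_steps_rejected(self):
        with pytest.raises(ValueError):
            Schedule([ScheduleEvent(5, ("E", "E"), 8.0), ScheduleEvent(2, ("E", "E"), 8.0)])


class TestPairRng:
    def test_symmetric_in_pair_order(self):
        assert pair_rng(3, 7, 11, 5) == pair_rng(7, 3, 11, 5)

    def test_stream_statistics(self):
        steps = np.arange(1_000_000, dtype=np.int64)
        draws = _kernels.pair_rng_stream(3, 7, steps, 12345)
        n = len(draws)
        # mean within 4 standard errors of 0; variance within 2% of 1
        assert abs(draws.mean()) < 4.0 / np.sqrt(n)
        assert abs(draws.var() - 1.0) < 0.02
        # bounded support of the uniform variate
        assert np.abs(draws).max() <= np.sqrt(3.0) + 1e-12

    def test_steps_uncorrelated(self):
        steps = np.arange(1_000_000, dtype=np.int64)
        draws = _kernels.pair_rng_stream(1, 2, steps, 99)
        rho = np.corrcoef(draws[:-1], draws[1:])[0, 1]
        assert abs(rho) < 0.01

    def test_distinct_beads_required(self):
        with pytest.raises(ValueError):
            pair_rng(4, 4, 0, 0)
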