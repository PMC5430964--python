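"""Trap-hop HMM: emissions, Viterbi decoding, count-matching iteration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from traphop.hmm import (DecodingError, StepModel, TrapHopHMM,
                         barrier_from_p, build_transition_matrix,
                         detection_floor, emissions, empirical_transitions,
                         find_local_minima, fit_p_trap, greedy_decode,
                         reduced_chi2, scan_step_size, viterbi_decode,
                         viterbi_iterate)
from traphop.synthetic import (SynthConfig, synth_traphop,
                               synth_traphop_two_scale, synth_trapped)


def brute_force_best_path(v, T):
    """Exhaustive max-product oracle over all (N+1)^T paths."""
    n_frames, n_states = v.shape
    best_p, best_path = -1.0, None
    for path in itertools.product(range(n_states), repeat=n_frames):
        p = v[0, path[0]]
        for t in range(1, n_frames):
            p *= T[path[t - 1], path[t]] * v[t, path[t]]
        if p > best_p:
            best_p, best_path = p, path
    return best_p, best_path


def path_probability(path, v, T):
    p = v[0, path[0]]
    for t in range(1, len(path)):
        p *= T[path[t - 1], path[t]] * v[t, path[t]]
    return p


class TestEmissions:
    def test_exact_level_is_maximal_with_weight_one(self):
        m = StepModel(step_size_g=0.84, w_trap=0.31, n_steps=3)
        v = emissions(np.array([2 * 0.84]), m)
        assert v[0, 2] == pytest.approx(1.0)
        assert np.argmax(v[0]) == 2

    def test_midpoint_symmetry(self):
        m = StepModel(step_size_g=0.84, w_trap=0.31, n_steps=3)
        v = emissions(np.array([1.5 * 0.84]), m)
        assert v[0, 1] == pytest.approx(v[0, 2])

    def test_half_step_value(self):
        # r = g/2 against level 0: exp[-(0.42/0.31)^2]
        m = StepModel(step_size_g=0.84, w_trap=0.31, n_steps=1)
        v = emissions(np.array([0.42]), m)
        assert v[0, 0] == pytest.approx(math.exp(-((0.42 / 0.31) ** 2)))
        assert v[0, 0] == pytest.approx(math.exp(-1.83558), rel=1e-4)


class TestTransitionMatrix:
    @pytest.mark.parametrize("p", [0.0, 0.3, 0.7, 1.0])
    @pytest.mark.parametrize("n_steps", [1, 3, 10])
    def test_structure_and_row_stochasticity(self, p, n_steps):
        T = build_transition_matrix(p, n_steps).entries
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        # tridiagonal: zero beyond the first off-diagonals
        for i in range(n_steps + 1):
            for j in range(n_steps + 1):
                if abs(i - j) > 1:
                    assert T[i, j] == 0.0
        assert np.allclose(np.diag(T), p)
        if n_steps >= 2:
            assert T[1, 0] == T[1, 2] == pytest.approx((1 - p) / 2)
        assert T[0, 1] == pytest.approx(1 - p)
        assert T[n_steps, n_steps - 1] == pytest.approx(1 - p)


class TestViterbi:
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        n_states = data.draw(st.integers(2, 4))
        n_frames = data.draw(st.integers(1, 8))
        p_trap = data.draw(st.floats(0.05, 0.95))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        m = StepModel(step_size_g=1.0, w_trap=0.4, n_steps=n_states - 1)
        r = rng.uniform(-0.5, n_states - 0.5, size=n_frames)
        v = emissions(r, m)
        T = build_transition_matrix(p_trap, m.n_steps)
        decoded = viterbi_decode(v, T)
        best_p, _ = brute_force_best_path(v, T.entries)
        got_p = path_probability(decoded.states, v, T.entries)
        assert got_p == pytest.approx(best_p, rel=1e-9)

    def test_constant_displacement_decodes_constant_path(self):
        m = StepModel(step_size_g=0.84, w_trap=0.31, n_steps=4)
        v = emissions(np.full(20, 2 * 0.84), m)
        path = viterbi_decode(v, build_transition_matrix(0.9, 4))
        assert np.all(path.states == 2)

    def test_p_trap_one_freezes_initial_level(self):
        m = StepModel(step_size_g=1.0, w_trap=0.3, n_steps=3)
        r = np.array([0.0, 1.0, 2.0, 3.0])  # later frames prefer neighbours
        path = viterbi_decode(emissions(r, m), build_transition_matrix(1.0, 3))
        assert np.all(path.states == path.states[0])

    def test_tie_breaks_to_lower_index(self):
        m = StepModel(step_size_g=1.0, w_trap=0.3, n_steps=2)
        v = emissions(np.array([0.5, 0.5]), m)  # levels 0 and 1 exactly tied
        path = viterbi_decode(v, build_transition_matrix(0.5, 2))
        assert path.states[0] == 0


class TestEmpiricalTransitions:
    def test_direct_counting(self):
        T_star, visited, counts = empirical_transitions([0, 0, 1, 1], 1)
        assert T_star[0, 0] == pytest.approx(0.5)
        assert T_star[0, 1] == pytest.approx(0.5)
        assert T_star[1, 1] == pytest.approx(1.0)
        assert visited.all()
        assert counts.sum() == 3

    def test_constant_path_identity_row(self):
        T_star, visited, _ = empirical_transitions(np.zeros(10, int), 2)
        assert T_star[0, 0] == 1.0
        assert not visited[1] and not visited[2]

    def test_lln_convergence_to_generating_matrix(self):
        # frequencies of a Markov chain sampled from a known T approach T
        T = build_transition_matrix(0.7, 3).entries
        rng = np.random.default_rng(17)
        devs = []
        for n in (1000, 10_000):
            states = np.zeros(n, dtype=int)
            for t in range(1, n):
                states[t] = rng.choice(4, p=T[states[t - 1]])
            T_star, visited, _ = empirical_transitions(states, 3)
            devs.append(np.abs(T_star[visited] - T[visited]).max())
        assert devs[1] < devs[0]


class TestFitPTrap:
    def test_exact_tridiagonal_recovered(self):
        T = build_transition_matrix(0.7, 3).entries
        assert fit_p_trap(T, 3) == pytest.approx(0.7, abs=1e-5)

    def test_identity_gives_one(self):
        assert fit_p_trap(np.eye(4), 3) == pytest.approx(1.0, abs=1e-5)

    def test_matches_grid_search_oracle(self):
        # hand-built empirical matrix with mixed diagonals
        T_star = np.array([[0.6, 0.4, 0.0],
                           [0.1, 0.8, 0.1],
                           [0.0, 0.3, 0.7]])
        got = fit_p_trap(T_star, 2)
        grid = np.linspace(0, 1, 10_001)
        norms = [np.linalg.norm(T_star - build_transition_matrix(p, 2).entries)
                 for p in grid]
        assert got == pytest.approx(grid[int(np.argmin(norms))], abs=1e-4)

    def test_no_transitions_is_an_error(self):
        with pytest.raises(DecodingError):
            fit_p_trap(np.zeros((3, 3)), 2)


class TestReducedChi2:
    def test_exact_match_is_zero(self):
        T = build_transition_matrix(0.8, 1)
        assert reduced_chi2(T, T.entries) == 0.0

    def test_two_state_worked_example(self):
        # diag 0.8/off 0.2 vs observed 0.7/0.3, nu = 4 - 3 = 1:
        # 2*(0.01/0.7) + 2*(0.01/0.3) = 0.0952
        T = build_transition_matrix(0.8, 1)
        T_star = np.array([[0.7, 0.3], [0.3, 0.7]])
        assert reduced_chi2(T, T_star) == pytest.approx(0.0952, abs=2e-4)

    def test_degenerate_dof_raises(self):
        T = build_transition_matrix(0.8, 1)
        T_star = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(DecodingError):
            reduced_chi2(T, T_star)


class TestViterbiIteration:
    def test_parameter_recovery_at_study_conditions(self):
        # median over seeds of the recovered trapping probability
        outs = []
        for seed in range(20):
            traj = synth_traphop(SynthConfig(p_trap=0.7, seed=seed))
            res = TrapHopHMM(traj, step_size_g=0.84, w_trap=0.31).fit()
            outs.append(res.p_trap_star)
        assert abs(np.median(outs) - 0.7) < 0.05

    def test_hop_free_trajectory_gives_p_near_one(self):
        traj = synth_trapped(0.31, 0.1, 3.0, 3000.0, seed=2)
        res = TrapHopHMM(traj, step_size_g=0.84, w_trap=0.31, n_steps=3).fit()
        assert res.p_trap_star >= 0.99

    def test_independent_of_starting_guess(self):
        # two starts each converge within tol of the same fixed point
        for seed in (0, 1, 2):
            traj = synth_traphop(SynthConfig(p_trap=0.7, seed=seed))
            m = TrapHopHMM(traj, step_size_g=0.84, w_trap=0.31)
            lo = m.fit(p0=0.1, tol=1e-3)
            hi = m.fit(p0=0.95, tol=1e-3)
            assert abs(lo.p_trap_star - hi.p_trap_star) < 2e-3

    def test_chi2_near_one_on_self_generated_data(self):
        chis = [
            TrapHopHMM(synth_traphop(SynthConfig(p_trap=0.6, seed=s)),
                       step_size_g=0.84, w_trap=0.31).fit().chi2_over_nu
            for s in range(10)
        ]
        assert 0.4 < np.median(chis) < 2.0

    def test_greedy_baseline_fits_worse(self):
        vit, greedy = [], []
        for s in range(10):
            m = TrapHopHMM(synth_traphop(SynthConfig(p_trap=0.7, seed=s)),
                           step_size_g=0.84, w_trap=0.31)
            vit.append(m.fit().chi2_over_nu)
            greedy.append(m.fit_greedy().chi2_over_nu)
        assert np.median(greedy) > np.median(vit)

    def test_summary_contains_estimates(self):
        traj = synth_traphop(SynthConfig(p_trap=0.7, seed=1))
        res = TrapHopHMM(traj, step_size_g=0.84, w_trap=0.31).fit()
        s = res.summary()
        assert "P_trap*" in s and "chi2" in s
        d = res.to_dict()
        assert 0 <= d["p_trap_star"] <= 1
        assert d["delta_G_kBT"] == pytest.approx(
            -math.log(1 - d["p_trap_star"]))


class TestStepSizeScan:
    def test_monotone_trajectory_with_constant_increments(self):
        # every move is exactly g0 (one stay between moves keeps the fitted
        # trapping probability interior); disable the Nyquist floor
        g0 = 0.8
        r = np.repeat(np.arange(20), 2) * g0
        table = scan_step_size(r, [0.5 * g0, g0, 1.5 * g0], w_trap=0.2,
                               p_floor=0.0)
        best = table.loc[table["chi2_over_nu"].idxmin()]
        assert best["g"] == pytest.approx(g0)

    def test_minimum_near_generating_step_size(self):
        traj = synth_traphop(SynthConfig(p_trap=0.6, seed=6, duration=6000))
        grid = np.arange(0.5, 1.45, 0.1)
        table = scan_step_size(traj.displacement, grid, w_trap=0.31)
        ok = table[~table.below_floor]
        best_g = ok.loc[ok["chi2_over_nu"].idxmin(), "g"]
        assert abs(best_g - 0.84) <= 0.1 + 1e-9

    def test_two_scale_mixture_flags_multiple_minima(self):
        traj = synth_traphop_two_scale(
            SynthConfig(p_trap=0.7, seed=1, duration=6000))
        grid = np.arange(0.55, 1.5, 0.09)
        table = scan_step_size(traj.displacement, grid, w_trap=0.31)
        flagged = table[table.local_min & ~table.below_floor]
        assert len(flagged) >= 2

    def test_local_minima_detector(self):
        v = np.array([3.0, 1.0, 2.0, np.nan, 2.0, 0.5, 0.9])
        flags = find_local_minima(v)
        assert flags[1] and flags[5]
        assert not flags[0] and not flags[2]


class TestBarrierAndFloor:
    @pytest.mark.parametrize("p, dg", [(0.55, 0.8), (0.6, 0.9), (0.75, 1.4)])
    def test_printed_barrier_values(self, p, dg):
        assert barrier_from_p(p) == pytest.approx(dg, abs=0.05)

    def test_exact_unit_barrier(self):
        assert barrier_from_p(1 - math.exp(-1)) == pytest.approx(1.0)

    def test_infinite_barrier_sentinel(self):
        assert math.isinf(barrier_from_p(1.0))

    @given(st.floats(0.01, 0.98), st.floats(0.01, 0.98))
    def test_monotone_in_p_trap(self, a, b):
        lo, hi = sorted((a, b))
        assert barrier_from_p(lo) <= barrier_from_p(hi)

    def test_detection_floor_values(self):
        # dt * f_Nyq = 2 -> exp(-2) = 0.135
        assert detection_floor(2.0, 2.0) == pytest.approx(0.1353, abs=1e-4)
        assert detection_floor(0.0, 2.0) == 1.0

    def test_floor_flag_raised_for_fast_hopper(self):
        traj = synth_traphop(SynthConfig(p_trap=0.05, seed=0,
                                         frame_interval=3.0, duration=3000.0))
        res = TrapHopHMM(traj, step_size_g=0.84, w_trap=0.31).fit()
        if res.p_trap_star < detection_floor(3.0, 1 / 3.0):
            assert res.below_detection_floor
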