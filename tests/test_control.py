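"""Riccati recursion, cost-to-go, width schedules, replanning."""

import numpy as np
import pytest

from costgo.control import (
    CostSchedule, TargetSpec, WidthSchedule, backward_recursion,
    build_terminal_Q, control_command, cost_to_go, lqr_backward, replan,
    target_vector, width_weight, with_target,
)
from costgo.plant import CORE_DIM, IDX, build_plant

from oracles import batch_lqr_solution, random_system, rollout_cost


class TestBackwardRecursion:
    def test_scalar_single_step_by_hand(self):
        """A=B=R=Q_N=1, N=1: L = 0.5 and S_0 = 0.5."""
        sched = CostSchedule(Q=np.array([[1.0]]), R=np.array([[1.0]]), N=1)
        sol = lqr_backward(np.array([[1.0]]), np.array([[1.0]]), sched)
        assert sol.L[0, 0, 0] == pytest.approx(0.5)
        assert sol.S[0, 0, 0] == pytest.approx(0.5)

    def test_matches_batch_quadratic_program(self):
        """Gains and cost agree with the stacked closed-form solution < 1e-8."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = rng.integers(1, 5)
            m = rng.integers(1, n + 1)
            N = int(rng.integers(1, 11))
            A, B, QN, R = random_system(rng, n, m)
            Qs = [np.zeros((n, n))]
            for _ in range(N - 1):
                W = rng.normal(size=(n, n)) * rng.integers(0, 2)  # some zero
                Qs.append(W @ W.T)
            Qs.append(QN)
            x0 = rng.normal(size=n)
            sched = CostSchedule(Q=Qs, R=R, N=N)
            sol = lqr_backward(A, B, sched)
            U_batch, cost_batch = batch_lqr_solution(A, B, Qs, R, N, x0)
            # commands along the rollout match the batch minimizer
            x = x0.copy()
            for t in range(N):
                u = -sol.L[t] @ x
                np.testing.assert_allclose(u, U_batch[t], atol=1e-8)
                x = A @ x + B @ u
            assert cost_to_go(sol, x0, 0) == pytest.approx(cost_batch, abs=1e-8)

    def test_offsets_zero_without_noise_or_bias(self, plant):
        target = TargetSpec(shape="point")
        sched = CostSchedule(Q=build_terminal_Q(target), R=1e-4 * np.eye(2), N=20)
        sol = backward_recursion(plant, sched)
        np.testing.assert_array_equal(sol.s, np.zeros(21))

    def test_terminal_bias_shifts_offsets_only(self, noisy_plant):
        """r_N moves every s_t by exactly r_N; gains and S stay bit-identical."""
        target = TargetSpec(shape="point")
        Q = build_terminal_Q(target)
        base = backward_recursion(noisy_plant, CostSchedule(Q=Q, R=1e-4 * np.eye(2), N=25))
        biased = backward_recursion(
            noisy_plant, CostSchedule(Q=Q, R=1e-4 * np.eye(2), N=25, terminal_bias=0.05))
        np.testing.assert_array_equal(base.L, biased.L)
        np.testing.assert_array_equal(base.S, biased.S)
        np.testing.assert_allclose(biased.s - base.s, np.full(26, 0.05), atol=1e-15)

    def test_offsets_accumulate_noise_trace(self, noisy_plant):
        target = TargetSpec(shape="point")
        sched = CostSchedule(Q=build_terminal_Q(target), R=1e-4 * np.eye(2), N=10)
        sol = backward_recursion(noisy_plant, sched)
        manual = [0.0]
        for t in range(10, 0, -1):
            manual.insert(0, manual[0] + np.trace(sol.S[t] @ noisy_plant.Sigma_m_core))
        np.testing.assert_allclose(sol.s, manual, rtol=1e-12)

    def test_indefinite_R_rejected(self):
        with pytest.raises(ValueError):
            CostSchedule(Q=np.eye(2), R=np.zeros((1, 1)), N=3).validate()


class TestCostToGo:
    def test_quadratic_form_direct(self):
        from costgo.control import ControlSolution
        sol = ControlSolution(L=np.zeros((1, 1, 2)),
                              S=np.stack([np.eye(2), np.eye(2)]),
                              s=np.array([0.5, 0.5]))
        assert cost_to_go(sol, np.array([1.0, 2.0]), 0) == pytest.approx(5.5)

    def test_zero_deviation_zero_value(self, plant):
        target = TargetSpec(position=(0.1, 0.25), shape="point")
        sched = CostSchedule(Q=build_terminal_Q(target), R=1e-4 * np.eye(2), N=15)
        sol = backward_recursion(plant, sched)
        x = with_target(np.zeros(CORE_DIM), target_vector(target))
        x[:2] = target.position  # on target, at rest
        assert cost_to_go(sol, x, 15) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_value_equals_realized_remaining_cost(self, plant):
        """v̂(x̂, t) equals the rollout cost of the optimal policy to < 1e-8."""
        target = TargetSpec(position=(0.0, 0.25), shape="point")
        Q = build_terminal_Q(target)
        R = 1e-4 * np.eye(2)
        N = 30
        sol = backward_recursion(plant, CostSchedule(Q=Q, R=R, N=N))
        Qs = [np.zeros((CORE_DIM, CORE_DIM))] * N + [Q]
        x0 = with_target(np.zeros(CORE_DIM), target_vector(target))
        realized = rollout_cost(plant.A_core, plant.B_core, Qs, R, sol, x0, N)
        assert cost_to_go(sol, x0, 0) == pytest.approx(realized, abs=1e-8)

    def test_command_is_linear_and_zero_at_origin(self, plant):
        target = TargetSpec(shape="point")
        sched = CostSchedule(Q=build_terminal_Q(target), R=1e-4 * np.eye(2), N=10)
        sol = backward_recursion(plant, sched)
        assert np.allclose(control_command(sol, np.zeros(CORE_DIM), 0), 0.0)
        x = np.random.default_rng(8).normal(size=CORE_DIM)
        np.testing.assert_allclose(control_command(sol, 3.0 * x, 2),
                                   3.0 * control_command(sol, x, 2), atol=1e-12)

    def test_wide_target_ignores_transverse_displacement(self, plant):
        """w2 = 0: no corrective x-command for a pure lateral offset."""
        target = TargetSpec(position=(0.0, 0.25), shape="wide", w2=0.0)
        sched = CostSchedule(Q=build_terminal_Q(target), R=1e-4 * np.eye(2), N=20)
        sol = backward_recursion(plant, sched)
        x = with_target(np.zeros(CORE_DIM), target_vector(target))
        x[IDX["px"]] = 0.03
        u = control_command(sol, x, 0)
        assert abs(u[0]) < 1e-12


class TestTerminalQ:
    def test_narrow_on_target_zero(self):
        t = TargetSpec(position=(0.02, 0.25), shape="narrow", w1=3.0)
        Q = build_terminal_Q(t)
        x = with_target(np.zeros(CORE_DIM), target_vector(t))
        x[:2] = t.position
        assert x @ Q @ x == pytest.approx(0.0)

    def test_transverse_error_weighted_by_w2(self):
        """1 cm transverse miss at w2 = 100 costs 100 * 0.01^2 = 0.01."""
        t = TargetSpec(position=(0.0, 0.25), shape="wide", w2=100.0)
        Q = build_terminal_Q(t)
        x = with_target(np.zeros(CORE_DIM), target_vector(t))
        x[:2] = (0.01, 0.25)
        assert x @ Q @ x == pytest.approx(0.01)

    def test_wide_form_invariant_to_transverse_translation(self):
        t = TargetSpec(position=(0.0, 0.25), shape="wide", w2=0.0)
        Q = build_terminal_Q(t)
        x = with_target(np.zeros(CORE_DIM), target_vector(t))
        x[:2] = (0.0, 0.25)
        for dx in (0.05, -0.2, 1.0):
            shifted = x.copy()
            shifted[IDX["px"]] += dx
            assert shifted @ Q @ shifted == pytest.approx(x @ Q @ x)


class TestWidthSchedule:
    def test_sigmoid_values_at_midpoint(self):
        slow = WidthSchedule(condition="slow", w2_base=100.0)
        fast = WidthSchedule(condition="fast", w2_base=100.0)
        assert width_weight(slow, 10) == pytest.approx(0.05)
        assert width_weight(fast, 10) == pytest.approx(0.5)

    def test_fast_is_ten_times_slow_everywhere(self):
        slow = WidthSchedule(condition="slow")
        fast = WidthSchedule(condition="fast")
        for t in np.linspace(-5, 60, 27):
            assert width_weight(fast, t) == pytest.approx(10 * width_weight(slow, t))

    def test_sigmoid_nondecreasing(self):
        sched = WidthSchedule(condition="fast")
        vals = [width_weight(sched, t) for t in range(0, 60)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_switch_steps_at_zero(self):
        sw = WidthSchedule(condition="switch", pre_value=0.0, post_value=100.0)
        assert width_weight(sw, -1) == 0.0
        assert width_weight(sw, 0) == 100.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            WidthSchedule(condition="warp")


class TestReplan:
    def test_time_invariant_replanning_reproduces_offline_lqg(self, plant):
        """Per-step MPC with constant parameters equals one offline solve < 1e-9."""
        target = TargetSpec(position=(0.0, 0.25), shape="point")
        Q = build_terminal_Q(target)
        R = 1e-4 * np.eye(2)
        N = 40
        offline = backward_recursion(plant, CostSchedule(Q=Q, R=R, N=N))
        x_off = with_target(np.zeros(CORE_DIM), target_vector(target))
        x_mpc = x_off.copy()
        for t in range(N):
            u_off = -offline.L[t] @ x_off
            sol = replan(plant, Q, R, remaining_N=N - t)
            u_mpc = -sol.L[0] @ x_mpc
            x_off = plant.A_core @ x_off + plant.B_core @ u_off
            x_mpc = plant.A_core @ x_mpc + plant.B_core @ u_mpc
        assert np.max(np.abs(x_off - x_mpc)) < 1e-9

    def test_final_step_reduces_to_single_iteration(self, plant):
        target = TargetSpec(shape="point")
        Q = build_terminal_Q(target)
        sol = replan(plant, Q, 1e-4 * np.eye(2), remaining_N=1)
        assert sol.N == 1
        np.testing.assert_array_equal(sol.S[1], Q)

    def test_replan_requires_remaining_horizon(self, plant):
        with pytest.raises(ValueError):
            replan(plant, np.eye(CORE_DIM), np.eye(2), remaining_N=0)


def test_value_never_below_terminal_bias(noisy_plant):
    """With PSD Q, PD R, PSD noise and bias >= 0, v̂ >= bias everywhere."""
    rng = np.random.default_rng(11)
    target = TargetSpec(shape="point")
    sched = CostSchedule(Q=build_terminal_Q(target), R=1e-4 * np.eye(2), N=20,
                         terminal_bias=0.03)
    sol = backward_recursion(noisy_plant, sched)
    for _ in range(100):
        x = rng.normal(scale=0.3, size=CORE_DIM)
        t = int(rng.integers(0, 21))
        assert cost_to_go(sol, x, t) >= 0.03 - 1e-12
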