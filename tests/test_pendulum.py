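"""Frontal-plane inverted-pendulum model: dynamics, limit cycles, optimization."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from splitgait.pendulum import (DivergenceError, OptimizationError,
                                PendulumConfig, analytic_step, optimize_split_old,
                                optimize_split_young, optimize_tied, simulate,
                                single_offset_residuals, trajectory_summary)

OMEGA = math.sqrt(9.81)


def integrate_step(u0, v0, omega, T, cop_rate=0.0, rtol=1e-12, atol=1e-14):
    """High-accuracy numerical oracle for one stance phase."""
    def rhs(t, s):
        return [s[1], omega**2 * (s[0] - cop_rate * t)]
    sol = solve_ivp(rhs, (0.0, T), [u0, v0], rtol=rtol, atol=atol, dense_output=True)
    return sol.y[0, -1], sol.y[1, -1]


class TestAnalyticStep:
    def test_equilibrium_on_cop_is_fixed(self):
        assert analytic_step(0.0, 0.0, OMEGA, 0.8) == (0.0, 0.0)

    def test_hyperbolic_closed_form_values(self):
        # omega=1, T=ln 2: cosh = 1.25, sinh = 0.75
        u, v = analytic_step(0.1, 0.0, 1.0, math.log(2.0))
        assert u == pytest.approx(0.125, abs=1e-12)
        assert v == pytest.approx(0.075, abs=1e-12)

    @pytest.mark.parametrize("u0,v0,omega,T,c", [
        (0.1, 0.0, 1.0, math.log(2.0), 0.0),
        (0.02, -0.15, OMEGA, 0.68, 0.0),
        (-0.05, 0.3, OMEGA, 0.51, 0.019),
        (0.01, 0.1, 2.5, 0.61, -0.05),
        (0.0, 0.0, OMEGA, 0.5, 0.02),
    ])
    def test_matches_numerical_integrator(self, u0, v0, omega, T, c):
        u_ref, v_ref = integrate_step(u0, v0, omega, T, c)
        u, v = analytic_step(u0, v0, omega, T, cop_rate=c)
        assert u == pytest.approx(u_ref, abs=1e-9)
        assert v == pytest.approx(v_ref, abs=1e-9)


class TestSimulate:
    def test_rest_on_foot_with_zero_offset_is_fixed_point(self):
        cfg = PendulumConfig(offsets={"fast": 0.0, "slow": 0.0})
        traj = simulate(cfg, 60)
        assert np.all(np.abs(traj.step_widths) < 1e-12)
        assert np.all(np.abs(traj.boundary_states[:, 0]) < 1e-12)

    def test_one_step_equals_analytic_step_plus_placement_rule(self):
        cfg = PendulumConfig(initial_state=(0.03, -0.1), initial_foot=0.05,
                             first_stance_side="slow", cop_rate=0.01,
                             burn_in_strides=0)
        traj = simulate(cfg, 4)
        T = cfg.durations["fast"]  # first placement is the fast foot
        du, dv = analytic_step(0.03 - 0.05, -0.1, cfg.omega, T, cop_rate=0.01)
        u1, v1 = 0.05 + du, dv
        p1 = u1 + v1 / cfg.omega + cfg.offsets["fast"]
        assert traj.boundary_states[1] == pytest.approx([u1, v1], abs=1e-12)
        assert traj.placements[0] == pytest.approx(p1, abs=1e-12)

    def test_tied_limit_cycle_reaches_constant_step_width(self):
        b, T = 0.0154, 0.68
        cfg = PendulumConfig(durations={"fast": T, "slow": T},
                             offsets={"fast": b, "slow": b})
        traj = simulate(cfg, 80)
        late = traj.step_widths[-20:]
        assert np.max(np.abs(late - late.mean())) < 1e-8
        # closed form of the dead-beat stride map
        assert late.mean() == pytest.approx(b * (1 + math.exp(OMEGA * T)), abs=1e-8)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_tied_limit_cycle_matches_return_map_root(self):
        """Independent oracle: fixed point of the two-step return map."""
        b, T = 0.02, 0.5
        omega = OMEGA

        def two_step_map(state):
            u, v = state  # CoM relative to current stance foot (side s)
            for sigma_new in (+1.0, -1.0):  # step onto left, then right
                u, v = analytic_step(u, v, omega, T)
                p_new = u + v / omega + sigma_new * b
                u = u - p_new  # relative to the new foot
            return np.asarray([u, v]) - np.asarray(state)

        fixed = fsolve(two_step_map, x0=[-0.01, 0.1], full_output=False, xtol=1e-13)
        # step width implied by the fixed point
        u, v = fixed
        u1, v1 = analytic_step(u, v, omega, T)
        width_oracle = abs(u1 + v1 / omega + b)
        cfg = PendulumConfig(durations={"fast": T, "slow": T},
                             offsets={"fast": b, "slow": b})
        traj = simulate(cfg, 80)
        assert traj.step_widths[-10:].mean() == pytest.approx(width_oracle, abs=1e-8)

    def test_simulate_agrees_with_sequential_integration(self):
        cfg = PendulumConfig(durations={"fast": 0.61, "slow": 0.51},
                             offsets={"fast": 0.0258, "slow": 0.0176},
                             cop_rate=0.005)
        n = 100  # 50 strides
        traj = simulate(cfg, n)
        u, v = cfg.initial_state
        p = cfg.initial_foot
        stance = cfg.first_stance_side
        for k in range(n):
            side = "slow" if stance == "fast" else "fast"
            T = cfg.durations[side]
            du, dv = integrate_step(u - p, v - 0.0, cfg.omega, T, cfg.cop_rate)
            u, v = p + du, dv
            p = u + v / cfg.omega + (1.0 if side == "fast" else -1.0) * cfg.offsets[side]
            stance = side
        assert traj.placements[-1] == pytest.approx(p, abs=1e-8)

    def test_divergent_state_raises(self):
        cfg = PendulumConfig(initial_state=(0.5, 1.5))
        with pytest.raises(DivergenceError):
            simulate(cfg, 50)


class TestOptimization:
    def test_tied_slow_and_fast_reach_goals(self):
        for T, goal in ((0.68, 0.145), (0.50, 0.135)):
            b = optimize_tied(T, goal)
            cfg = PendulumConfig(durations={"fast": T, "slow": T},
                                 offsets={"fast": b, "slow": b})
            s = trajectory_summary(simulate(cfg, 80))
            assert s.mean_step_width == pytest.approx(goal, abs=1e-4)
            # independent closed form for the dead-beat stride map
            assert b == pytest.approx(goal / (1 + math.exp(OMEGA * T)), abs=1e-6)

    def test_zero_width_goal_gives_zero_offset(self):
        assert optimize_tied(0.6, 0.0) == pytest.approx(0.0, abs=1e-6)

    def test_split_young_two_offsets_satisfy_both_constraints(self):
        b_fast, b_slow = optimize_split_young(0.61, 0.51, 0.145)
        cfg = PendulumConfig(durations={"fast": 0.61, "slow": 0.51},
                             offsets={"fast": b_fast, "slow": b_slow})
        s = trajectory_summary(simulate(cfg, 80))
        assert s.mean_step_width == pytest.approx(0.145, abs=1e-4)
        assert abs(s.drift_per_stride) < 1e-5
        assert b_fast > b_slow

    def test_split_young_equal_durations_reduces_to_tied(self):
        b_fast, b_slow = optimize_split_young(0.6, 0.6, 0.14)
        b_tied = optimize_tied(0.6, 0.14)
        assert b_fast == pytest.approx(b_slow, abs=1e-6)
        assert b_fast == pytest.approx(b_tied, abs=1e-5)

    def test_split_old_needs_nonzero_cop_rate(self):
        b, c = optimize_split_old(0.61, 0.51, 0.145)
        assert abs(c) > 1e-3
        cfg = PendulumConfig(durations={"fast": 0.61, "slow": 0.51},
                             offsets={"fast": b, "slow": b}, cop_rate=c)
        s = trajectory_summary(simulate(cfg, 80))
        assert s.mean_step_width == pytest.approx(0.145, abs=1e-4)
        assert abs(s.drift_per_stride) < 1e-5

    def test_split_old_equal_durations_recovers_zero_rate(self):
        b, c = optimize_split_old(0.55, 0.55, 0.14)
        assert c == pytest.approx(0.0, abs=1e-6)

    def test_frozen_cop_rate_is_infeasible_for_split(self):
        with pytest.raises(OptimizationError):
            optimize_split_old(0.61, 0.51, 0.145, fix_cop_rate=0.0)


class TestTrajectorySummary:
    def test_periodic_tied_orbit_has_no_drift_or_com_offset(self):
        b = optimize_tied(0.68, 0.145)
        cfg = PendulumConfig(durations={"fast": 0.68, "slow": 0.68},
                             offsets={"fast": b, "slow": b})
        s = trajectory_summary(simulate(cfg, 80))
        assert abs(s.drift_per_stride) < 1e-10
        assert abs(s.com_midline_offset) < 1e-10

    def test_young_solution_shifts_com_toward_slow_side(self):
        b_fast, b_slow = optimize_split_young(0.61, 0.51, 0.145)
        cfg = PendulumConfig(durations={"fast": 0.61, "slow": 0.51},
                             offsets={"fast": b_fast, "slow": b_slow})
        s = trajectory_summary(simulate(cfg, 80))
        # ML positive toward the fast (left) belt: toward slow is negative
        assert s.com_midline_offset < -1e-3

    def test_old_solution_keeps_com_on_the_midline(self):
        b, c = optimize_split_old(0.61, 0.51, 0.145)
        cfg = PendulumConfig(durations={"fast": 0.61, "slow": 0.51},
                             offsets={"fast": b, "slow": b}, cop_rate=c)
        s = trajectory_summary(simulate(cfg, 80))
        assert abs(s.com_midline_offset) < 1e-3

    def test_too_few_strides_raises(self):
        cfg = PendulumConfig(burn_in_strides=0,
                             offsets={"fast": 0.01, "slow": 0.01})
        traj = simulate(cfg, 2)
        with pytest.raises(ValueError):
            trajectory_summary(traj)


def test_single_offset_drift_residual_bounded_away_from_zero():
    """Grid-search oracle for the feasibility dichotomy."""
    grid = np.linspace(0.0, 0.05, 26)
    res = single_offset_residuals(0.61, 0.51, 0.145, grid)
    assert res.min() > 1e-3
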