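"""Periodic-gait search, the optimal push-off, sweeps, and tuning relations."""

import math

import numpy as np
import pytest

from springwalker.dynamics import SectionState, total_energy
from springwalker.errors import (
    GaitRangeError,
    InsufficientDataError,
    NoGaitError,
)
from springwalker.periodic import (
    find_fixed_point,
    find_stiffness_for_gait,
    map_step,
    nondimensional_speed,
    optimal_push_off,
    poincare_map,
    sweep_stiffness,
    tuning_relations,
)


def push_off_theta_form(s, v, mu, beta):
    """Independent oracle: the stance-angle form of the optimal push-off."""
    theta = -math.asin(s / 2.0)
    theta_dot = v / math.cos(theta)
    return (-theta_dot * math.tan(theta) * (2 * beta * math.cos(theta) ** 2 + 1)
            + mu / (2 * theta_dot * math.cos(theta)))


class TestOptimalPushOff:
    def test_two_printed_forms_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            s = rng.uniform(0.05, 0.95)
            v = rng.uniform(0.05, 0.95)
            mu = rng.uniform(0.0, 0.3)
            assert optimal_push_off(s, v, mu, 0.074) == pytest.approx(
                push_off_theta_form(s, v, mu, 0.074), abs=1e-12)

    def test_short_step_limit(self):
        v, mu = 0.4, 0.142
        assert optimal_push_off(1e-9, v, mu, 0.074) == pytest.approx(
            mu / (2 * v), rel=1e-6)

    def test_positive_without_gravity_share(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = rng.uniform(0.05, 0.95)
            v = rng.uniform(0.05, 0.95)
            assert optimal_push_off(s, v, 0.0, 0.074) > 0

    @pytest.mark.parametrize("s,v", [(0.0, 0.4), (1.2, 0.4), (0.5, 0.0),
                                     (0.5, 1.0)])
    def test_range_errors(self, s, v):
        with pytest.raises(GaitRangeError):
            optimal_push_off(s, v, 0.142, 0.074)


class TestWorkedExampleGait:
    """The step-length 0.6, speed 0.39 periodic gait of the walking model."""

    def test_targets_reproduced(self, worked_gait):
        assert worked_gait.s == pytest.approx(0.6, abs=1e-8)
        assert worked_gait.v == pytest.approx(0.39, abs=1e-8)
        assert worked_gait.residual < 1e-8

    def test_spring_constant_regression(self, worked_gait):
        # frozen from this implementation (value not printed anywhere);
        # guards against silent changes in the solver or dynamics
        assert worked_gait.k_star == pytest.approx(0.145612, abs=2e-5)

    def test_map_fixed_point(self, worked_gait, params):
        q = worked_gait.section_state()
        q1 = poincare_map(q, worked_gait.k_star, params)
        defect = math.hypot(q1.theta - q.theta, q1.theta_dot - q.theta_dot)
        assert defect < 1e-8
        q2 = poincare_map(q1, worked_gait.k_star, params)
        assert q2.theta == pytest.approx(q.theta, abs=1e-7)

    def test_map_continuity_under_perturbation(self, worked_gait, params):
        q = worked_gait.section_state()
        drifts = []
        for delta in (1e-3, 1e-4):
            qp = SectionState(q.theta + delta, q.theta_dot)
            q1 = poincare_map(qp, worked_gait.k_star, params)
            drifts.append(math.hypot(q1.theta - q.theta, q1.theta_dot - q.theta_dot))
        assert drifts[0] < 0.05
        assert drifts[1] < drifts[0]

    def test_pushoff_closed_form_at_fixed_point(self, worked_gait, params):
        closed = optimal_push_off(worked_gait.s, worked_gait.v, params.mu, params.beta)
        assert worked_gait.i_push == pytest.approx(closed, abs=1e-8)

    def test_speed_restored_and_energy_conserved(self, worked_gait, params):
        q = worked_gait.section_state()
        q_next, traj, _ = map_step(q, worked_gait.k_star, params)
        assert traj.pre_collision.theta_dot == pytest.approx(
            q.theta_dot, abs=1e-8)
        p = params.with_stiffness(worked_gait.k_star)
        e_post = total_energy(q.to_full(), p)
        e_pre = total_energy(traj.pre_collision, p)
        e_next = total_energy(q_next.to_full(), p)
        assert e_pre == pytest.approx(e_post, abs=1e-8)
        assert e_next == pytest.approx(e_post, abs=1e-8)


class TestFixedPointSearch:
    def test_springless_walker_has_unit_swing_frequency(self, params):
        gait = find_fixed_point(0.399, 0.0, params)
        assert gait.omega == 1.0
        assert gait.residual < 1e-8

    def test_stiffness_rises_with_speed_at_fixed_step_length(self, params):
        k_lo = find_stiffness_for_gait(0.6, 0.35, params).k_star
        k_hi = find_stiffness_for_gait(0.6, 0.43, params).k_star
        assert k_hi > k_lo

    def test_degenerate_step_length_rejected(self, params):
        with pytest.raises((GaitRangeError, NoGaitError)):
            find_stiffness_for_gait(1e-9, 0.39, params)

    def test_out_of_range_speed_rejected(self, params):
        with pytest.raises(GaitRangeError):
            find_fixed_point(1.2, 0.1, params)


class TestSweep:
    def test_single_point_grid_matches_direct_solve(self, params):
        v = nondimensional_speed(1.25)
        sweep = sweep_stiffness(v, [0.15], params)
        direct = find_fixed_point(v, 0.15, params)
        assert len(sweep.gaits) == 1
        assert sweep.gaits[0].theta_star == pytest.approx(
            direct.theta_star, abs=1e-10)

    def test_observables_monotone_in_stiffness(self, params):
        v = nondimensional_speed(1.00)
        sweep = sweep_stiffness(v, np.arange(0.02, 0.25, 0.02), params)
        assert len(sweep.gaits) >= 8
        assert np.all(np.diff(sweep.observable("T")) > 0)
        assert np.all(np.diff(sweep.observable("F")) < 0)
        assert np.all(np.diff(sweep.observable("b")) < 0)
        assert np.all(np.diff(sweep.observable("s")) < 0)

    def test_torque_slope_decreases_along_sweep(self, params):
        v = nondimensional_speed(1.00)
        sweep = sweep_stiffness(v, np.arange(0.02, 0.25, 0.02), params)
        slopes = np.diff(sweep.observable("T")) / np.diff(sweep.converged_k)
        assert np.all(np.diff(slopes) < 0)

    def test_speeds_match_target(self, params):
        v = nondimensional_speed(0.75)
        sweep = sweep_stiffness(v, np.arange(0.05, 0.2, 0.05), params)
        for g in sweep.gaits:
            assert g.v == pytest.approx(v, abs=1e-9)


class TestTuningRelations:
    def test_requires_three_gaits(self, worked_gait):
        with pytest.raises(InsufficientDataError):
            tuning_relations([worked_gait, worked_gait])

    def test_frequency_proportionality_on_small_sweep(self, params):
        v = nondimensional_speed(1.25)
        sweep = sweep_stiffness(v, np.arange(0.02, 0.3, 0.04), params)
        rel = tuning_relations(sweep.gaits)
        assert rel.omega_r2 > 0.98
        assert rel.omega_slope > 0

    def test_deviation_definition(self, worked_gait):
        rel = tuning_relations([worked_gait] * 3)
        expected = abs(worked_gait.tau - worked_gait.s / worked_gait.v) / worked_gait.tau
        assert rel.median_tau_deviation == pytest.approx(expected, rel=1e-12)
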