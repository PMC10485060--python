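"""Equations of motion, energy, swing integration, and the jump map."""

import math

import numpy as np
import pytest

from springwalker.dynamics import (
    SectionState,
    TransitionImpulses,
    WalkerParams,
    WalkerState,
    collision_transition,
    eom_rhs,
    full_transition,
    gravity_impulse,
    integrate_swing,
    linearized_rhs,
    mechanical_energy,
    natural_frequency,
    total_energy,
)
from springwalker.errors import (
    InvalidParameterError,
    InvalidStateError,
    NoCollisionError,
)


def sympy_accelerations(theta, phi, theta_dot, phi_dot, k, beta):
    """Independent oracle: symbolic 2x2 solve of the equations of motion."""
    import sympy as sp

    th, ph, thd, phd = sp.symbols("th ph thd phd")
    m = sp.Matrix([[1 + beta, beta * sp.cos(th + ph)],
                   [beta * sp.cos(th + ph), beta]])
    cor = sp.Matrix([-beta * sp.sin(th + ph) * phd**2,
                     -beta * sp.sin(th + ph) * thd**2])
    grav = sp.Matrix([-(1 + beta) * sp.sin(th), beta * sp.sin(ph)])
    ext = sp.Matrix([0, -k * ph])
    acc = m.solve(ext - cor - grav)
    subs = {th: theta, ph: phi, thd: theta_dot, phd: phi_dot}
    return float(acc[0].subs(subs)), float(acc[1].subs(subs))


class TestEomRhs:
    def test_upright_rest_is_equilibrium(self, params):
        d = eom_rhs(WalkerState(0.0, 0.0, 0.0, 0.0), params)
        assert np.allclose(d, 0.0)

    @pytest.mark.parametrize("state,k", [
        ((0.1, 0.0, 0.0, 0.0), 0.0),
        ((0.15, -0.2, 0.3, -0.4), 0.1),
        ((-0.3, 0.25, 0.45, 0.6), 0.05),
    ])
    def test_matches_symbolic_solve(self, state, k):
        beta = 0.074
        p = WalkerParams(beta=beta, k=k)
        d = eom_rhs(WalkerState(*state), p)
        thdd, phdd = sympy_accelerations(*state, k=k, beta=beta)
        assert d[2] == pytest.approx(thdd, rel=1e-12)
        assert d[3] == pytest.approx(phdd, rel=1e-12)

    def test_leaning_accelerations_magnitudes(self, params):
        # frozen from the symbolic oracle at (theta=0.1, rest), k=0
        d = eom_rhs(WalkerState(0.1, 0.0, 0.0, 0.0), WalkerParams(k=0.0))
        assert d[2] == pytest.approx(0.107144, abs=5e-6)
        assert d[3] == pytest.approx(-0.106609, abs=5e-6)

    def test_rejects_non_finite_state(self, params):
        with pytest.raises(InvalidStateError):
            eom_rhs(WalkerState(math.nan, 0.0, 0.0, 0.0), params)

    def test_linearization_consistency(self, params):
        """Relative disagreement vanishes as the state amplitude shrinks."""
        base = np.array([0.8, -0.5, 0.6, -0.9])
        errors = []
        for scale in (1e-1, 1e-2, 1e-3):
            y = base * scale
            nl = eom_rhs(WalkerState(*y), params)[2:]
            lin = linearized_rhs(WalkerState(*y), params)[2:]
            errors.append(np.max(np.abs(nl - lin)) / np.max(np.abs(nl)))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-5


class TestLinearizedRhs:
    def test_swing_only_deflection(self):
        # solving the linear pair by hand: phidd = -(1+b) w^2 phi0,
        # thdd = -(b/(1+b)) phidd
        p = WalkerParams(beta=0.074, k=0.05)
        w2 = 1.0 + p.k / p.beta
        phi0 = 0.07
        d = linearized_rhs(WalkerState(0.0, phi0, 0.0, 0.0), p)
        assert d[3] == pytest.approx(-(1 + p.beta) * w2 * phi0, rel=1e-12)
        assert d[2] == pytest.approx(-(p.beta / (1 + p.beta)) * d[3], rel=1e-12)

    def test_stance_only_deflection_springless(self):
        p = WalkerParams(beta=0.074, k=0.0)
        th0 = 0.1
        d = linearized_rhs(WalkerState(th0, 0.0, 0.0, 0.0), p)
        assert d[2] == pytest.approx((1 + p.beta) * th0, rel=1e-12)

    def test_zero_state(self, params):
        assert np.allclose(linearized_rhs(WalkerState(0, 0, 0, 0), params), 0.0)


class TestNaturalFrequency:
    @pytest.mark.parametrize("k_over_beta,omega", [(0.0, 1.0), (3.0, 2.0),
                                                   (1.0, math.sqrt(2))])
    def test_closed_form(self, k_over_beta, omega):
        beta = 0.074
        p = WalkerParams(beta=beta, k=k_over_beta * beta)
        assert natural_frequency(p) == pytest.approx(omega, rel=1e-14)

    def test_invalid_beta(self):
        with pytest.raises(InvalidParameterError):
            WalkerParams(beta=0.0)


class TestEnergy:
    def test_upright_rest_energy(self, params):
        q = SectionState(theta=0.0, theta_dot=1e-12)
        assert mechanical_energy(q, params) == pytest.approx(1.0)

    def test_increasing_in_speed(self, params):
        qs = [SectionState(-0.3, td) for td in (0.1, 0.3, 0.5)]
        es = [mechanical_energy(q, params) for q in qs]
        assert es[0] < es[1] < es[2]

    def test_section_formula_equals_point_mass_energy(self):
        """Oracle: direct kinematic energy from the two point masses."""
        rng = np.random.default_rng(7)
        p = WalkerParams(k=0.08)
        for _ in range(20):
            q = SectionState(theta=rng.uniform(-0.45, -0.05),
                             theta_dot=rng.uniform(0.05, 0.7))
            th, td = q.theta, q.theta_dot
            phd = -td * math.cos(2 * th)
            # hip at (sin th, cos th); swing foot at (sin th + sin phi,
            # cos th - cos phi) with phi = th on the section
            v_hip = np.array([math.cos(th) * td, -math.sin(th) * td])
            v_foot = v_hip + np.array([math.cos(th) * phd, math.sin(th) * phd])
            ke = 0.5 * v_hip @ v_hip + 0.5 * p.beta * (v_foot @ v_foot)
            pe = math.cos(th) + p.beta * 0.0 + 0.5 * p.k * th**2
            assert mechanical_energy(q, p) == pytest.approx(ke + pe, rel=1e-12)


class TestIntegrateSwing:
    def test_worked_example_trajectory_is_symmetric(self, worked_gait, params):
        p = params.with_stiffness(worked_gait.k_star)
        traj = integrate_swing(worked_gait.section_state(), p)
        assert traj.pre_collision.theta == pytest.approx(
            -worked_gait.theta_star, abs=1e-6)

    def test_energy_conserved_along_swing(self, worked_gait, params):
        p = params.with_stiffness(worked_gait.k_star)
        traj = integrate_swing(worked_gait.section_state(), p)
        e = [total_energy(traj.state_at(i), p)
             for i in range(0, len(traj.times), 50)]
        assert np.max(np.abs(np.array(e) - e[0])) < 1e-8

    def test_midswing_scuff_is_ignored(self, worked_gait, params):
        p = params.with_stiffness(worked_gait.k_star)
        traj = integrate_swing(worked_gait.section_state(), p)
        assert len(traj.scuff_times) == 1
        assert 0.0 < traj.scuff_times[0] < traj.tau

    def test_non_walking_state_raises(self, params):
        with pytest.raises(NoCollisionError):
            integrate_swing(SectionState(theta=-0.05, theta_dot=0.9),
                            params.with_stiffness(0.0))

    def test_backward_motion_rejected(self, params):
        with pytest.raises(InvalidStateError):
            integrate_swing(SectionState(theta=-0.3, theta_dot=-0.1), params)


class TestTransition:
    def test_upright_zero_impulse_identity(self, params):
        pre = WalkerState(0.0, 0.0, 0.4, 0.1)
        q = collision_transition(pre, TransitionImpulses(0.0, 0.0, 0.0), params)
        assert q.theta_dot == pytest.approx(0.4, rel=1e-14)

    def test_massless_feet_limit_is_classical_loss(self):
        p = WalkerParams(beta=1e-9)
        th = 0.3
        pre = WalkerState(th, th, 0.5, -0.2)
        q = collision_transition(pre, TransitionImpulses(0.0, 0.0, 0.0), p)
        assert q.theta_dot == pytest.approx(0.5 * math.cos(2 * th), rel=1e-6)

    def test_row_consistency_on_random_states(self, params):
        """phi_dot+ = -theta_dot+ cos(2 theta+) for any impulses."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            th = rng.uniform(0.05, 0.45)
            pre = WalkerState(th, th, rng.uniform(0.1, 0.8), rng.uniform(-1, 1))
            imp = TransitionImpulses(rng.uniform(0, 0.5), rng.uniform(0, 0.5),
                                     rng.uniform(0, 0.5))
            post = full_transition(pre, imp, params)
            assert post.phi == pytest.approx(post.theta, abs=1e-14)
            assert post.phi_dot == pytest.approx(
                -post.theta_dot * math.cos(2 * post.theta), rel=1e-12)

    def test_collision_condition_enforced(self, params):
        pre = WalkerState(0.3, 0.1, 0.5, -0.2)
        with pytest.raises(InvalidStateError):
            collision_transition(pre, TransitionImpulses(0.0, 0.0, 0.0), params)


class TestGravityImpulse:
    @pytest.mark.parametrize("mu,td,expected", [
        (0.142, 0.142, 1.0),
        (0.0, 0.5, 0.0),
        (0.142, 0.4, 0.355),
    ])
    def test_inverse_law(self, mu, td, expected):
        imp = gravity_impulse(td, mu)
        assert imp.i_gravity == pytest.approx(expected, rel=1e-12)
        assert imp.dt_ds == imp.i_gravity

    def test_rejects_non_forward_motion(self):
        with pytest.raises(InvalidStateError):
            gravity_impulse(0.0, 0.142)
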