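"""Dynamics of the powered simple walking model.

The walker is the classical compass-gait biped: two massless legs of length
``l`` hinged at a point-mass hip ``M``, a point mass ``m`` at each foot, and a
torsional spring of stiffness ``k`` between the (always vertical) trunk and the
swing leg.  All quantities are dimensionless in the basis ``M = l = 1`` with
time unit ``sqrt(l/g)``, so the only inertial parameter is the mass ratio
``beta = m/M``.

Configuration variables:

* ``theta`` — stance-leg angle from the vertical, positive clockwise (the hip
  moves along +x as ``theta`` increases);
* ``phi``   — swing-leg angle from the trunk, positive counterclockwise.

A step is one single-support (swing) phase, terminated by the heel-strike
condition ``theta - phi = 0``, followed by an instantaneous transition in which
a push-off impulse along the trailing leg and a vertical gravitational impulse
(gravity integrated over the double-support period) are applied just before a
perfectly inelastic collision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    InvalidParameterError,
    InvalidStateError,
    NoCollisionError,
)

__all__ = [
    "WalkerParams",
    "WalkerState",
    "SectionState",
    "StepTrajectory",
    "TransitionImpulses",
    "eom_rhs",
    "linearized_rhs",
    "natural_frequency",
    "integrate_swing",
    "collision_transition",
    "full_transition",
    "gravity_impulse",
    "mechanical_energy",
    "total_energy",
]

#: Angle beyond which the walker is considered fallen (stance leg horizontal).
_FALL_ANGLE = math.pi / 2


@dataclass(frozen=True)
class WalkerParams:
    """Dimensionless model constants and numerics settings.

    Parameters
    ----------
    beta
        Foot-to-hip mass ratio ``m/M``; default 0.074 (lower-limb inertia
        matched to anthropometric data).
    k
        Hip spring constant (dimensionless torque per radian).
    mu
        Proportionality constant of the double-support law
        ``dt_ds = mu / theta_dot_pre``; default 0.142, the mean value
        estimated from treadmill walking.
    integ_rel_tol, integ_abs_tol
        Relative/absolute tolerances of the swing-phase integrator.
    event_tol
        Tolerance to which the heel-strike root ``theta - phi = 0`` is located.
    max_step_time
        Cap on the swing duration; exceeding it raises
        :class:`~springwalker.errors.NoCollisionError`.
    """

    beta: float = 0.074
    k: float = 0.0
    mu: float = 0.142
    integ_rel_tol: float = 1e-10
    integ_abs_tol: float = 1e-12
    event_tol: float = 1e-10
    max_step_time: float = 50.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")
        if not (np.isfinite(self.k) and self.k >= 0):
            raise InvalidParameterError(f"k must be >= 0, got {self.k}")
        if not (np.isfinite(self.mu) and self.mu >= 0):
            raise InvalidParameterError(f"mu must be >= 0, got {self.mu}")
        for name in ("integ_rel_tol", "integ_abs_tol", "event_tol", "max_step_time"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be > 0, got {v}")

    def with_stiffness(self, k: float) -> "WalkerParams":
        return replace(self, k=float(k))


@dataclass(frozen=True)
class WalkerState:
    """Full state ``(theta, phi, theta_dot, phi_dot)`` of the walker."""

    theta: float
    phi: float
    theta_dot: float
    phi_dot: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.phi, self.theta_dot, self.phi_dot])

    @classmethod
    def from_array(cls, y) -> "WalkerState":
        y = np.asarray(y, dtype=float)
        return cls(theta=y[0], phi=y[1], theta_dot=y[2], phi_dot=y[3])

    def validate(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise InvalidStateError(f"non-finite walker state {self}")


@dataclass(frozen=True)
class SectionState:
    """Post-collision Poincaré state ``q = (theta, theta_dot)``.

    The section is taken just after heel strike, where the remaining
    coordinates are slaved to ``q``: ``phi = theta`` and
    ``phi_dot = -theta_dot * cos(2 theta)``.
    """

    theta: float
    theta_dot: float

    def to_full(self) -> WalkerState:
        return WalkerState(
            theta=self.theta,
            phi=self.theta,
            theta_dot=self.theta_dot,
            phi_dot=-self.theta_dot * math.cos(2.0 * self.theta),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.theta_dot])

    def validate(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise InvalidStateError(f"non-finite section state {self}")
        if self.theta_dot <= 0:
            raise InvalidStateError(
                f"forward walking requires theta_dot > 0, got {self.theta_dot}"
            )


@dataclass(frozen=True)
class TransitionImpulses:
    """Impulses applied just before heel strike.

    ``i_gravity`` equals the double-support period ``dt_ds = mu/theta_dot_pre``
    (gravity integrated over double support, acting on the hip mass only);
    ``i_push`` acts along the trailing leg.
    """

    i_push: float
    i_gravity: float
    dt_ds: float


@dataclass
class StepTrajectory:
    """Sampled swing-phase trajectory of one step.

    ``times`` runs from 0 to the step period ``tau``; ``states`` holds one row
    ``(theta, phi, theta_dot, phi_dot)`` per sample.  ``pre_collision`` is the
    event-located state at heel strike; ``scuff_times`` lists ignored
    ``theta - phi = 0`` crossings (foot grazing the ground mid-swing).
    """

    times: np.ndarray
    states: np.ndarray
    tau: float
    pre_collision: WalkerState
    scuff_times: list = field(default_factory=list)

    def state_at(self, index: int) -> WalkerState:
        return WalkerState.from_array(self.states[index])


# ---------------------------------------------------------------------------
# Equations of motion
# ---------------------------------------------------------------------------

def _rhs_nonlinear(t, y, k, beta):
    """Right-hand side of the full equations of motion.

    The accelerations solve the 2x2 linear system with mass matrix
    ``[[1+b, b c], [b c, b]]`` (``c = cos(theta+phi)``) by closed-form
    inversion; the determinant ``b(1+b) - b^2 c^2 >= b > 0`` for ``b > 0``.
    """
    th, ph, thd, phd = y
    c = math.cos(th + ph)
    s = math.sin(th + ph)
    det = beta * (1.0 + beta) - beta * beta * c * c
    # right-hand side = external torque - Coriolis/centrifugal - gravity
    b1 = beta * s * phd * phd + (1.0 + beta) * math.sin(th)
    b2 = beta * s * thd * thd - beta * math.sin(ph) - k * ph
    thdd = (beta * b1 - beta * c * b2) / det
    phdd = (-beta * c * b1 + (1.0 + beta) * b2) / det
    return (thd, phd, thdd, phdd)


def _rhs_linearized(t, y, k, beta):
    """Right-hand side of the small-angle equations of motion.

    Solving the linearized pair
    ``thdd + beta/(1+beta) phdd - theta = 0`` and
    ``phdd + thdd + omega^2 phi = 0`` (``omega^2 = 1 + k/beta``) gives
    ``phdd = -(1+beta)(theta + omega^2 phi)`` and
    ``thdd = theta + beta (theta + omega^2 phi)``.
    """
    th, ph, thd, phd = y
    w2 = 1.0 + k / beta
    g = th + w2 * ph
    return (thd, phd, th + beta * g, -(1.0 + beta) * g)


_RHS = {"nonlinear": _rhs_nonlinear, "linearized": _rhs_linearized}


def eom_rhs(state: WalkerState, params: WalkerParams) -> np.ndarray:
    """Full-model state derivative ``(theta_dot, phi_dot, theta_ddot, phi_ddot)``."""
    state.validate()
    return np.array(_rhs_nonlinear(0.0, state.as_array(), params.k, params.beta))


def linearized_rhs(state: WalkerState, params: WalkerParams) -> np.ndarray:
    """Small-angle state derivative; agrees with :func:`eom_rhs` to first order."""
    state.validate()
    return np.array(_rhs_linearized(0.0, state.as_array(), params.k, params.beta))


def natural_frequency(params: WalkerParams) -> float:
    """Natural frequency of the swing leg, ``omega = sqrt(1 + k/beta) >= 1``."""
    return math.sqrt(1.0 + params.k / params.beta)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def mechanical_energy(q: SectionState, params: WalkerParams) -> float:
    """Mechanical energy of the post-collision state.

    ``E = 1/2 (1 + beta sin^2 2theta) theta_dot^2 + cos theta + 1/2 k theta^2``
    — kinetic energy, gravitational potential, spring potential.  Equals
    :func:`total_energy` of the reconstructed full state.
    """
    q.validate()
    s2 = math.sin(2.0 * q.theta)
    return (
        0.5 * (1.0 + params.beta * s2 * s2) * q.theta_dot**2
        + math.cos(q.theta)
        + 0.5 * params.k * q.theta**2
    )


def total_energy(state: WalkerState, params: WalkerParams) -> float:
    """Full-state mechanical energy (conserved during single support).

    Kinetic energy of the hip mass and the swing-foot mass plus gravitational
    potential of both masses plus the spring potential ``1/2 k phi^2``.  The
    stance foot is the (massless-velocity) pivot at the origin; the hip sits at
    ``(sin theta, cos theta)`` and the swing foot at
    ``(sin theta + sin phi, cos theta - cos phi)``.
    """
    state.validate()
    th, ph, thd, phd = state.theta, state.phi, state.theta_dot, state.phi_dot
    b = params.beta
    ke = 0.5 * thd * thd + 0.5 * b * (
        thd * thd + phd * phd + 2.0 * thd * phd * math.cos(th + ph)
    )
    pe = (1.0 + b) * math.cos(th) - b * math.cos(ph) + 0.5 * params.k * ph * ph
    return ke + pe


# ---------------------------------------------------------------------------
# Swing-phase integration with heel-strike detection
# ---------------------------------------------------------------------------

def integrate_swing(
    q: SectionState,
    params: WalkerParams,
    model: str = "nonlinear",
    n_samples: int = 2000,
) -> StepTrajectory:
    """Integrate one swing phase from the post-collision section state.

    Integration runs until the first *accepted* heel-strike event.  The event
    function ``g = theta - phi`` vanishes at the start of the step (the section
    lies on the collision manifold), so detection is armed only after ``g``
    leaves a dead-band of ``10 * event_tol``.  A crossing is accepted as heel
    strike only when it is a rising crossing (``dg/dt > 0``) with ``theta > 0``
    — the stance leg behind the vertical, as required for a positive step
    length.  Falling crossings (the swing foot grazing the ground as the legs
    pass each other mid-swing) and rising crossings with ``theta <= 0`` are
    recorded in ``scuff_times`` and ignored.

    Raises
    ------
    NoCollisionError
        If the walker falls (``|theta| >= pi/2``) or no accepted event occurs
        before ``max_step_time``.
    """
    q.validate()
    if model not in _RHS:
        raise InvalidParameterError(f"model must be one of {sorted(_RHS)}")
    rhs = _RHS[model]
    args = (params.k, params.beta)

    y0 = q.to_full().as_array()
    t0 = 0.0

    # leave the collision manifold before arming event detection
    deadband = 10.0 * params.event_tol
    dt_nudge = 1e-6
    for _ in range(60):
        sol0 = solve_ivp(
            rhs, (t0, t0 + dt_nudge), y0, args=args,
            rtol=params.integ_rel_tol, atol=params.integ_abs_tol,
            method="DOP853",
        )
        t0 = sol0.t[-1]
        y0 = sol0.y[:, -1]
        if abs(y0[0] - y0[1]) > deadband:
            break
        dt_nudge *= 2.0
    else:  # pragma: no cover - pathological zero-velocity start
        raise NoCollisionError("state never leaves the collision manifold")

    def rising(t, y, k, beta):
        return y[0] - y[1]

    rising.terminal = True
    rising.direction = 1

    def falling(t, y, k, beta):
        return y[0] - y[1]

    falling.terminal = False
    falling.direction = -1

    def fall_over(t, y, k, beta):
        return _FALL_ANGLE - abs(y[0])

    fall_over.terminal = True
    fall_over.direction = -1

    segments = []
    scuff_times: list = []
    while True:
        sol = solve_ivp(
            rhs, (t0, params.max_step_time), y0, args=args,
            rtol=params.integ_rel_tol, atol=params.integ_abs_tol,
            method="DOP853", dense_output=True,
            events=[rising, falling, fall_over],
        )
        segments.append(sol)
        scuff_times.extend(float(t) for t in sol.t_events[1])
        if sol.t_events[2].size > 0:
            raise NoCollisionError(
                f"walker fell at t={sol.t_events[2][0]:.4f} before heel strike"
            )
        if sol.t_events[0].size > 0:
            t_ev = float(sol.t_events[0][0])
            y_ev = sol.y_events[0][0]
            if y_ev[0] > 0.0:
                tau = t_ev
                pre = WalkerState.from_array(y_ev)
                break
            # rising crossing behind the vertical: a scuff; step over it
            scuff_times.append(t_ev)
            nudge = solve_ivp(
                rhs, (t_ev, t_ev + 1e-6), y_ev, args=args,
                rtol=params.integ_rel_tol, atol=params.integ_abs_tol,
                method="DOP853",
            )
            t0 = nudge.t[-1]
            y0 = nudge.y[:, -1]
            continue
        raise NoCollisionError(
            f"no heel strike before max_step_time={params.max_step_time}"
        )

    times = np.linspace(0.0, tau, n_samples)
    states = np.empty((n_samples, 4))
    states[0] = q.to_full().as_array()
    seg_bounds = [(seg.t[0], seg.t[-1], seg.sol) for seg in segments]
    for i, t in enumerate(times[1:], start=1):
        for lo, hi, interp in seg_bounds:
            if lo <= t <= hi:
                states[i] = interp(t)
                break
        else:
            # before the first segment (inside the nudge) or exactly tau
            states[i] = seg_bounds[0][2](max(t, seg_bounds[0][0])) \
                if t < seg_bounds[0][0] else pre.as_array()
    states[-1] = pre.as_array()
    return StepTrajectory(
        times=times, states=states, tau=tau, pre_collision=pre,
        scuff_times=sorted(scuff_times),
    )


# ---------------------------------------------------------------------------
# Step-to-step transition
# ---------------------------------------------------------------------------

def gravity_impulse(theta_dot_pre: float, mu: float) -> TransitionImpulses:
    """Gravitational impulse and double-support period, ``mu / theta_dot_pre``.

    Returned with ``i_push = 0``; callers fill in the push-off impulse.
    """
    if not (np.isfinite(theta_dot_pre) and theta_dot_pre > 0):
        raise InvalidStateError(
            f"theta_dot_pre must be > 0 for forward walking, got {theta_dot_pre}"
        )
    if mu < 0:
        raise InvalidParameterError(f"mu must be >= 0, got {mu}")
    ig = mu / theta_dot_pre
    return TransitionImpulses(i_push=0.0, i_gravity=ig, dt_ds=ig)


def _transition_rows(pre: WalkerState, imp: TransitionImpulses, beta: float):
    th = pre.theta
    thd = pre.theta_dot
    s2 = math.sin(2.0 * th)
    c2 = math.cos(2.0 * th)
    d = 1.0 + beta * s2 * s2
    theta_plus = -th
    theta_dot_plus = (
        c2 * thd + s2 * imp.i_push - math.sin(th) * imp.i_gravity
    ) / d
    phi_plus = -th
    phi_dot_plus = -c2 * theta_dot_plus
    return theta_plus, theta_dot_plus, phi_plus, phi_dot_plus


def collision_transition(
    pre: WalkerState, imp: TransitionImpulses, params: WalkerParams
) -> SectionState:
    """Apply the impulse-augmented heel-strike jump map to a pre-collision state.

    The pre-collision state must satisfy the collision condition
    ``theta - phi = 0`` (within ``10 * event_tol``).  Legs are relabelled
    (``theta+ = -theta-``), the push-off impulse acts along the trailing leg,
    the gravitational impulse acts vertically on the hip mass, and angular
    momentum is conserved through the perfectly inelastic collision.
    """
    pre.validate()
    if abs(pre.theta - pre.phi) > 10.0 * params.event_tol:
        raise InvalidStateError(
            "pre-collision state violates the collision condition: "
            f"|theta - phi| = {abs(pre.theta - pre.phi):.3e}"
        )
    th_p, thd_p, _, _ = _transition_rows(pre, imp, params.beta)
    return SectionState(theta=th_p, theta_dot=thd_p)


def full_transition(
    pre: WalkerState, imp: TransitionImpulses, params: WalkerParams
) -> WalkerState:
    """All four components of the post-collision state.

    The swing components satisfy ``phi+ = theta+`` and
    ``phi_dot+ = -theta_dot+ cos(2 theta+)`` identically for any impulses, so
    the full post state is the reconstruction of the section state returned by
    :func:`collision_transition`.
    """
    pre.validate()
    if abs(pre.theta - pre.phi) > 10.0 * params.event_tol:
        raise InvalidStateError(
            "pre-collision state violates the collision condition: "
            f"|theta - phi| = {abs(pre.theta - pre.phi):.3e}"
        )
    th_p, thd_p, ph_p, phd_p = _transition_rows(pre, imp, params.beta)
    return WalkerState(theta=th_p, phi=ph_p, theta_dot=thd_p, phi_dot=phd_p)
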