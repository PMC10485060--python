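"""Periodic-gait search on the optimal-push-off Poincaré map.

The Poincaré section is taken just after heel strike, where the state reduces
to ``q = (theta, theta_dot)``.  One application of the map integrates the
swing, computes the gravitational impulse from the double-support law, and
sizes the push-off impulse so that the collision energy loss is fully
compensated (``theta_dot+ = theta_dot-``, the optimal push-off hypothesis).

A periodic gait is a fixed point of this map.  Fixed points are located by a
shooting formulation: integrate from the reconstructed post-collision state
until the stance leg reaches the mirrored landing angle ``-theta+`` and demand
that the swing leg arrives there simultaneously (``theta - phi = 0``).  This
residual is smooth in both the stance angle and the spring constant, unlike a
first-collision residual, which jumps when the accepted event changes branch.

The landing residual admits spurious roots where the landing angle repeats but
the landing speed does not.  The physical gait family is the time-reversal
symmetric branch, on which the landing-speed defect ``theta_dot- - theta_dot+``
vanishes together with the landing residual; every candidate root is therefore
vetted against that defect before being accepted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .dynamics import (
    SectionState,
    StepTrajectory,
    TransitionImpulses,
    WalkerParams,
    _rhs_nonlinear,
    collision_transition,
    gravity_impulse,
    integrate_swing,
    mechanical_energy,
    natural_frequency,
)
from .errors import (
    GaitRangeError,
    InsufficientDataError,
    InvalidParameterError,
    NoGaitError,
    NonPhysicalPushOffWarning,
    SolverError,
    SweepError,
)
from .metrics import (
    check_gait_range,
    margin_of_stability,
    max_flexion_torque,
    propulsive_force,
    section_to_gait,
)

__all__ = [
    "PeriodicGait",
    "StiffnessSweep",
    "TuningRelations",
    "optimal_push_off",
    "poincare_map",
    "map_step",
    "find_fixed_point",
    "find_stiffness_for_gait",
    "sweep_stiffness",
    "tuning_relations",
    "NOMINAL_BELT_SPEEDS",
    "nondimensional_speed",
]

#: Belt speeds (m/s) studied in the treadmill protocol.
NOMINAL_BELT_SPEEDS = (0.50, 0.75, 1.00, 1.25, 1.50, 1.75)

#: Standard gravitational acceleration used for nondimensionalizing speeds.
GRAVITY = 9.81

#: Residual tolerance for the Newton iteration on the landing residual.
_NEWTON_TOL = 1e-10
#: Acceptance threshold on the landing-speed defect for the symmetric branch.
_SYMMETRY_TOL = 1e-6


def nondimensional_speed(speed_mps: float, g: float = GRAVITY) -> float:
    """Dimensionless walking speed ``v = speed / sqrt(g)`` (unit leg length)."""
    return speed_mps / math.sqrt(g)


def optimal_push_off(s: float, v: float, mu: float, beta: float) -> float:
    """Push-off impulse that exactly restores the collision energy loss.

    Closed form at a periodic gait with step length ``s`` and speed ``v``:
    ``i_push = s v (s^2 beta - 4 beta - 2)/(s^2 - 4) + mu/(2 v)``.
    The first term is positive on the admissible range (numerator and
    denominator both negative); the ``mu`` term is the push-off share spent
    against the gravitational impulse.
    """
    check_gait_range(s, v)
    return s * v * (s * s * beta - 4.0 * beta - 2.0) / (s * s - 4.0) + mu / (2.0 * v)


@dataclass(frozen=True)
class PeriodicGait:
    """A periodic gait (fixed point of the Poincaré map) and its observables."""

    theta_star: float
    theta_dot_star: float
    k_star: float
    s: float
    v: float
    tau: float
    omega: float
    phi_max: float
    T: float
    F: float
    b: float
    E: float
    i_push: float
    i_gravity: float
    dt_ds: float
    residual: float

    def section_state(self) -> SectionState:
        return SectionState(theta=self.theta_star, theta_dot=self.theta_dot_star)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class StiffnessSweep:
    """Fixed-speed continuation of periodic gaits over a stiffness grid."""

    v_target: float
    k_grid: np.ndarray
    gaits: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    @property
    def converged_k(self) -> np.ndarray:
        return np.array([g.k_star for g in self.gaits])

    def observable(self, name: str) -> np.ndarray:
        return np.array([getattr(g, name) for g in self.gaits])


@dataclass(frozen=True)
class TuningRelations:
    """Swing-tuning diagnostics over a collection of periodic gaits.

    ``omega_slope`` and ``omega_r2`` describe the origin-constrained linear fit
    of the swing natural frequency against the step frequency ``1/tau``;
    ``tau_deviations`` holds the relative deviations ``|tau - s/v| / tau`` of
    the inverted-pendulum period approximation.
    """

    omega_slope: float
    omega_r2: float
    tau_deviations: np.ndarray
    median_tau_deviation: float


# ---------------------------------------------------------------------------
# Poincaré map
# ---------------------------------------------------------------------------

def _solve_push_off(pre_theta, pre_theta_dot, i_gravity, beta) -> float:
    """Push-off impulse making the post-collision stance speed equal the
    pre-collision one (linear in ``i_push``, closed form)."""
    s2 = math.sin(2.0 * pre_theta)
    if abs(s2) < 1e-12:
        raise SolverError("degenerate collision geometry: sin(2 theta-) ~ 0")
    d = 1.0 + beta * s2 * s2
    c2 = math.cos(2.0 * pre_theta)
    return (pre_theta_dot * (d - c2) + math.sin(pre_theta) * i_gravity) / s2


def map_step(
    q: SectionState, k: float, params: WalkerParams, n_samples: int = 2000
) -> tuple[SectionState, StepTrajectory, TransitionImpulses]:
    """One full application of the Poincaré map, keeping the intermediates.

    Returns the next section state, the swing trajectory, and the transition
    impulses.  The push-off impulse is always chosen to restore
    ``theta_dot+ = theta_dot-``; a negative solution (non-physical push-off,
    the impulse would have to pull) is returned with a warning.
    """
    p = params.with_stiffness(k)
    traj = integrate_swing(q, p, n_samples=n_samples)
    pre = traj.pre_collision
    imp0 = gravity_impulse(pre.theta_dot, p.mu)
    i_push = _solve_push_off(pre.theta, pre.theta_dot, imp0.i_gravity, p.beta)
    if i_push < 0:
        warnings.warn(
            f"negative push-off impulse {i_push:.3e} required at theta-="
            f"{pre.theta:.4f}", NonPhysicalPushOffWarning, stacklevel=2,
        )
    imp = TransitionImpulses(
        i_push=i_push, i_gravity=imp0.i_gravity, dt_ds=imp0.dt_ds
    )
    q_next = collision_transition(pre, imp, p)
    return q_next, traj, imp


def poincare_map(q: SectionState, k: float, params: WalkerParams) -> SectionState:
    """Next post-collision state under the optimal-push-off step-to-step map."""
    q_next, _, _ = map_step(q, k, params, n_samples=2)
    return q_next


# ---------------------------------------------------------------------------
# Shooting residual
# ---------------------------------------------------------------------------

def _shoot(theta_plus: float, theta_dot_plus: float, k: float,
           params: WalkerParams):
    """Integrate from the section until the stance leg reaches ``-theta_plus``.

    Returns ``(t, state)`` at the passage, or ``None`` when the walker falls
    or the passage never happens.  The passage is unique for forward gaits
    (``theta_dot`` stays positive), which makes the residual
    ``theta - phi`` evaluated there smooth in both arguments.
    """
    q = SectionState(theta=theta_plus, theta_dot=theta_dot_plus)
    y0 = q.to_full().as_array()
    target = -theta_plus
    args = (k, params.beta)

    def passage(t, y, k, beta):
        return y[0] - target

    passage.terminal = True
    passage.direction = 1

    def fall_over(t, y, k, beta):
        return math.pi / 2 - abs(y[0])

    fall_over.terminal = True
    fall_over.direction = -1

    sol = solve_ivp(
        _rhs_nonlinear, (0.0, params.max_step_time), y0, args=args,
        rtol=params.integ_rel_tol, atol=params.integ_abs_tol,
        method="DOP853", events=[passage, fall_over],
    )
    if sol.t_events[0].size == 0:
        return None
    return float(sol.t_events[0][0]), sol.y_events[0][0]


def _landing_residual(theta_plus, theta_dot_plus, k, params):
    r = _shoot(theta_plus, theta_dot_plus, k, params)
    if r is None:
        return math.nan, math.nan, math.nan
    t, y = r
    return y[0] - y[1], y[2] - theta_dot_plus, t


# ---------------------------------------------------------------------------
# Gait construction
# ---------------------------------------------------------------------------

def _make_gait(theta_star: float, theta_dot_star: float, k: float,
               params: WalkerParams) -> PeriodicGait:
    q_star = SectionState(theta=theta_star, theta_dot=theta_dot_star)
    s, v = section_to_gait(q_star)
    q_next, traj, imp = map_step(q_star, k, params)
    residual = math.hypot(
        q_next.theta - theta_star, q_next.theta_dot - theta_dot_star
    )
    big_t, phi_max = max_flexion_torque(traj, k)
    force = (
        propulsive_force(s, v, params.mu, optimal_push_off(s, v, params.mu, params.beta))
        if params.mu > 0 else math.nan
    )
    return PeriodicGait(
        theta_star=theta_star,
        theta_dot_star=theta_dot_star,
        k_star=k,
        s=s,
        v=v,
        tau=traj.tau,
        omega=natural_frequency(params.with_stiffness(k)),
        phi_max=phi_max,
        T=big_t,
        F=force,
        b=margin_of_stability(s, v),
        E=mechanical_energy(q_star, params.with_stiffness(k)),
        i_push=imp.i_push,
        i_gravity=imp.i_gravity,
        dt_ds=imp.dt_ds,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# Fixed-point search
# ---------------------------------------------------------------------------

def _theta_dot_for_speed(theta_plus: float, v: float) -> float:
    return v / math.cos(theta_plus)


def find_fixed_point(
    v_target: float,
    k: float,
    params: WalkerParams,
    init_guess: float | None = None,
) -> PeriodicGait:
    """Periodic gait at a prescribed walking speed and spring constant.

    Solves the scalar landing residual over the post-collision stance angle
    ``theta+`` with ``theta_dot+ = v_target / cos(theta+)`` by Newton-Raphson
    (forward finite-difference derivative, step 1e-6 rad, half-step damping).
    ``init_guess`` seeds the iteration (continuation); without it the residual
    is bracketed by a coarse scan and candidate roots are vetted for the
    symmetric branch.
    """
    if not (0.0 < v_target < 1.0):
        raise GaitRangeError(f"v_target must lie in (0, 1), got {v_target}")
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")

    def residual(theta):
        return _landing_residual(
            theta, _theta_dot_for_speed(theta, v_target), k, params)[0]

    def diagnostics(theta):
        return _landing_residual(
            theta, _theta_dot_for_speed(theta, v_target), k, params)[1:]

    theta = None
    if init_guess is not None:
        theta = _newton_scalar(residual, init_guess)
        if theta is not None:
            dvel, _ = diagnostics(theta)
            if not (abs(dvel) < _SYMMETRY_TOL):
                theta = None  # converged to a non-symmetric root; rescan
    if theta is None:
        theta = _scan_for_root(residual, diagnostics,
                               grid=-np.linspace(0.012, 0.52, 48))
    if theta is None:
        raise SolverError(
            f"no symmetric periodic gait found for v={v_target}, k={k}",
            last_iterate=init_guess,
        )
    return _make_gait(theta, _theta_dot_for_speed(theta, v_target), k, params)


def _newton_scalar(residual, x0, tol=_NEWTON_TOL, fd_step=1e-6,
                   max_iter=50, max_damping=8):
    """Damped Newton-Raphson with forward finite-difference derivative.

    Returns the root or ``None`` on failure (NaN residual, zero derivative,
    or no convergence within ``max_iter``).
    """
    x = float(x0)
    r = residual(x)
    if not np.isfinite(r):
        return None
    for _ in range(max_iter):
        if abs(r) < tol:
            return x
        d = (residual(x + fd_step) - r) / fd_step
        if not np.isfinite(d) or d == 0.0:
            return None
        step = -r / d
        for _ in range(max_damping + 1):
            x_new = x + step
            r_new = residual(x_new)
            if np.isfinite(r_new) and abs(r_new) < abs(r):
                break
            step *= 0.5
        else:
            return None
        x, r = x_new, r_new
    return x if abs(r) < tol else None


def _scan_for_root(residual, diagnostics, grid):
    """Bracket-scan a residual and return the symmetric-branch root.

    Every sign change is polished with Brent's method and vetted against the
    landing-speed defect.  Several symmetric roots can coexist (secondary
    branches land after extra swing oscillations); the primary gait family is
    the branch whose swing lands at the first opportunity, so among vetted
    roots the one with the shortest step period is returned, or ``None`` when
    no symmetric root exists on the grid.
    """
    vals = np.array([residual(g) for g in grid])
    candidates = []
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb < 0:
            try:
                root = brentq(residual, a, b, xtol=1e-13)
            except ValueError:
                continue
            dvel, tau = diagnostics(root)
            if np.isfinite(dvel) and abs(dvel) < _SYMMETRY_TOL:
                candidates.append((tau, root))
    if not candidates:
        return None
    return min(candidates)[1]


def find_stiffness_for_gait(
    s_target: float,
    v_target: float,
    params: WalkerParams,
    k_max: float = 2.0,
) -> PeriodicGait:
    """Spring constant making a prescribed ``(s, v)`` pair a periodic gait.

    Fixes ``theta* = -asin(s/2)`` and ``theta_dot* = v / cos(theta*)`` and
    root-finds the landing residual over ``k``; the root on the symmetric
    branch is unique on the admissible range.
    """
    check_gait_range(s_target, v_target)
    theta_star = -math.asin(s_target / 2.0)
    theta_dot_star = v_target / math.cos(theta_star)

    def residual(k):
        return _landing_residual(theta_star, theta_dot_star, k, params)[0]

    def diagnostics(k):
        return _landing_residual(theta_star, theta_dot_star, k, params)[1:]

    grid = np.concatenate([
        [1e-6], np.linspace(0.01, 0.8, 41), np.linspace(0.85, k_max, 24),
    ])
    k_star = _scan_for_root(residual, diagnostics, grid)
    if k_star is None:
        raise NoGaitError(
            f"no symmetric periodic gait with s={s_target}, v={v_target} "
            f"for k in [0, {k_max}]"
        )
    return _make_gait(theta_star, theta_dot_star, k_star, params)


# ---------------------------------------------------------------------------
# Sweeps and tuning relations
# ---------------------------------------------------------------------------

def sweep_stiffness(
    v_target: float,
    k_grid,
    params: WalkerParams,
) -> StiffnessSweep:
    """Continuation of periodic gaits over an increasing stiffness grid.

    Each converged fixed point seeds the next grid point's Newton iteration;
    grid points without a gait in the admissible range (step length or speed
    outside (0, 1), or no symmetric root) are recorded as failures.
    """
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.ndim != 1 or k_grid.size == 0 or np.any(np.diff(k_grid) <= 0):
        raise InvalidParameterError("k_grid must be a non-empty increasing 1-D grid")
    sweep = StiffnessSweep(v_target=v_target, k_grid=k_grid)
    guess = None
    for k in k_grid:
        try:
            gait = find_fixed_point(v_target, float(k), params, init_guess=guess)
        except (SolverError, GaitRangeError, NoGaitError) as err:
            sweep.failures.append((float(k), f"{type(err).__name__}: {err}"))
            continue
        sweep.gaits.append(gait)
        guess = gait.theta_star
    if not sweep.gaits:
        raise SweepError(
            f"no grid point converged for v={v_target} on k in "
            f"[{k_grid[0]}, {k_grid[-1]}]"
        )
    return sweep


def tuning_relations(gaits) -> TuningRelations:
    """Swing-tuning diagnostics for a collection of periodic gaits.

    The swing natural frequency scales with the step frequency
    (``omega ∝ 1/tau``); the origin-constrained least-squares coefficient and
    its coefficient of determination quantify the proportionality.  The
    inverted-pendulum approximation ``tau ~ s/v`` is summarized by the
    distribution of relative deviations.
    """
    gaits = list(gaits)
    if len(gaits) < 3:
        raise InsufficientDataError(
            f"tuning relations need >= 3 gaits, got {len(gaits)}"
        )
    omega = np.array([g.omega for g in gaits])
    inv_tau = np.array([1.0 / g.tau for g in gaits])
    slope = float(inv_tau @ omega / (inv_tau @ inv_tau))
    ss_res = float(np.sum((omega - slope * inv_tau) ** 2))
    ss_tot = float(np.sum((omega - omega.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    dev = np.array([abs(g.tau - g.s / g.v) / g.tau for g in gaits])
    return TuningRelations(
        omega_slope=slope,
        omega_r2=r2,
        tau_deviations=dev,
        median_tau_deviation=float(np.median(dev)),
    )
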