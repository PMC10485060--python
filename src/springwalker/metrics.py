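"""Gait descriptors and model-side observables.

Converts between the Poincaré section state and the descriptors used for human
walking (step length ``s``, walking speed ``v``), and computes the observables
reported for each periodic gait: the margin of stability at heel strike, the
propulsive force generated by push-off, and the peak hip flexion torque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import SectionState, StepTrajectory
from .errors import GaitRangeError, InvalidParameterError, InvalidStateError

__all__ = [
    "MosDecomposition",
    "section_to_gait",
    "gait_to_section",
    "margin_of_stability",
    "mos_decomposition",
    "propulsive_force",
    "max_flexion_torque",
    "check_gait_range",
]


@dataclass(frozen=True)
class MosDecomposition:
    """Margin-of-stability decomposition at heel strike.

    ``x`` is the centre-of-mass position (the hip point mass), ``xi`` the
    extrapolated centre of mass ``x + v``, ``u`` the anterior boundary of the
    base of support ``x + s/2``, and ``b = u - xi`` the margin of stability.
    """

    x: float
    xi: float
    u: float
    b: float


def check_gait_range(s: float, v: float) -> None:
    """Validate ``0 < s < 1`` and ``0 < v < 1``."""
    if not (0.0 < s < 1.0):
        raise GaitRangeError(f"step length s must lie in (0, 1), got {s}")
    if not (0.0 < v < 1.0):
        raise GaitRangeError(f"walking speed v must lie in (0, 1), got {v}")


def section_to_gait(q: SectionState) -> tuple[float, float]:
    """Step length and walking speed of a post-collision state.

    ``s = -2 sin(theta+)`` (the landing foot is ``s`` ahead of the pivot) and
    ``v = theta_dot+ cos(theta+)`` (forward hip velocity at heel strike).
    """
    q.validate()
    s = -2.0 * math.sin(q.theta)
    v = q.theta_dot * math.cos(q.theta)
    check_gait_range(s, v)
    return s, v


def gait_to_section(s: float, v: float) -> SectionState:
    """Inverse of :func:`section_to_gait` on the admissible range."""
    check_gait_range(s, v)
    theta = -math.asin(s / 2.0)
    return SectionState(theta=theta, theta_dot=v / math.cos(theta))


def margin_of_stability(s: float, v: float) -> float:
    """Sagittal margin of stability at heel strike, ``b = s/2 - v``.

    The anterior base-of-support boundary sits half a step ahead of the
    centre of mass, and the extrapolated centre of mass adds the dimensionless
    forward velocity; their difference is independent of absolute position.
    """
    check_gait_range(s, v)
    return s / 2.0 - v


def mos_decomposition(x: float, s: float, v: float) -> MosDecomposition:
    """Full decomposition ``u = x + s/2``, ``xi = x + v``, ``b = u - xi``."""
    check_gait_range(s, v)
    u = x + s / 2.0
    xi = x + v
    return MosDecomposition(x=x, xi=xi, u=u, b=u - xi)


def propulsive_force(s: float, v: float, mu: float, i_push: float) -> float:
    """Propulsive force generated by push-off.

    The forward component of the push-off impulse divided by the
    double-support period:
    ``F = i_push sin(-theta*) / dt_ds = s v / (mu sqrt(4 - s^2)) * i_push``.
    Undefined for ``mu <= 0`` (no double-support period).
    """
    check_gait_range(s, v)
    if mu <= 0:
        raise InvalidParameterError(f"mu must be > 0 for a propulsive force, got {mu}")
    return s * v / (mu * math.sqrt(4.0 - s * s)) * i_push


def max_flexion_torque(traj: StepTrajectory, k: float) -> tuple[float, float]:
    """Peak hip flexion torque over one step and the extension angle at the peak.

    The spring torque on the swing leg is ``-k phi`` (positive = flexion).
    The discrete maximum over the sampled trajectory is refined by a 3-point
    quadratic fit around the argmax.  ``T = k * phi_max`` identically; for
    ``k = 0`` the torque vanishes and ``phi_max`` is reported as 0.
    """
    if traj.states.size == 0:
        raise InvalidStateError("empty trajectory")
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")
    if k == 0.0:
        return 0.0, 0.0
    torque = -k * traj.states[:, 1]
    i = int(np.argmax(torque))
    if 0 < i < len(torque) - 1:
        y0, y1, y2 = torque[i - 1], torque[i], torque[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # strictly concave triple: refine
            delta = 0.5 * (y0 - y2) / denom
            t_peak = y1 - 0.25 * (y0 - y2) * delta
        else:
            t_peak = y1
    else:
        t_peak = torque[i]
    big_t = float(t_peak)
    return big_t, big_t / k
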