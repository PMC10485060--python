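"""Synthetic treadmill trials driven by the walking model's periodic gaits.

Every trial is rolled out from a converged periodic gait of the simulator, so
each pipeline stage has exact ground truth: heel-strike times, step period and
length, pre-collision angular speed, double-support duration (from the inverse
law ``dt_ds = mu / theta_dot-``), hip torque-angle slope (the spring constant)
and the push-off propulsion peak (the model's propulsive force).

What is emulated: treadmill-frame marker motion (stance markers ride backwards
at belt speed), stride-to-stride timing jitter, finite double support in the
kinematics (a crossfade between consecutive single-support arcs, so that CoM
velocities do not jump instantaneously as they do in the hybrid model),
M-shaped vertical GRF with double-support overlap and clean 10 N / 0 N
crossings, biphasic anterior GRF whose propulsion peak equals the model's
propulsive force, a hip torque channel tied to the hip angle through the
spring law, and additive measurement noise (white on markers/forces/angles,
AR(1)-colored on the torque, emulating the non-elastic share of human hip
torque).

GRF contact intervals are shrunk by half a force-plate sample on each side so
that the threshold-based event detector is unbiased with respect to the stored
ground-truth event times.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .dynamics import WalkerParams
from .errors import InvalidParameterError
from .periodic import NOMINAL_BELT_SPEEDS, find_fixed_point, map_step
from .pipeline import SIDES, MocapTrial

__all__ = [
    "NoiseConfig",
    "SyntheticConfig",
    "generate_trial",
    "generate_cohort",
    "DEFAULT_K_BY_SPEED",
]

GRAVITY = 9.81

#: Cohort-level mean hip stiffness per nominal belt speed (rises with speed,
#: matching the progression observed in treadmill walking).
DEFAULT_K_BY_SPEED = {
    0.50: 0.08, 0.75: 0.10, 1.00: 0.12, 1.25: 0.14, 1.50: 0.15, 1.75: 0.16,
}

#: Minimum admissible stiffness per speed (below it no periodic gait with
#: step length < 1 exists at that dimensionless speed).
_K_FLOOR_BY_SPEED = {0.50: 0.02, 0.75: 0.02, 1.00: 0.02, 1.25: 0.02,
                     1.50: 0.02, 1.75: 0.11}


@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel additive measurement-noise scales.

    ``marker`` (m) applies to marker and CoM positions, ``grf`` (N) to both
    force components, and ``angle`` (rad) to the hip angle.  The hip-torque
    disturbance is AR(1)-colored with autoregression ``torque_ar`` per
    kinematic sample; its stationary standard deviation is
    ``torque + torque_rel * (k_true * phi_max * M g l)``, i.e. an absolute
    N·m share plus a share proportional to the trial's peak spring torque.
    The proportional share is deliberately large: it stands in for the
    non-spring-like share of human hip torque (not instrument noise), sized
    so the torque-angle fit quality matches the R^2 range observed in
    treadmill walking at every belt speed.
    """

    marker: float = 0.0003
    grf: float = 2.0
    angle: float = 0.003
    torque: float = 0.0
    torque_rel: float = 0.85
    torque_ar: float = 0.80

    @classmethod
    def zeros(cls) -> "NoiseConfig":
        return cls(marker=0.0, grf=0.0, angle=0.0, torque=0.0, torque_rel=0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic treadmill trial."""

    k_true: float = 0.12
    mu_true: float = 0.142
    nominal_speed: float = 1.25
    leg_length: float = 0.96
    subject_mass: float = 58.8
    n_strides: int = 35
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    stiffness_jitter: float = 0.12
    speed_jitter: float = 0.01
    belt_scale: float | None = None
    seed: int = 0
    kinematic_rate: float = 200.0
    grf_rate: float = 1000.0
    beta: float = 0.074
    subject_id: str = "S00"

    def __post_init__(self):
        if self.n_strides < 32:
            raise InvalidParameterError(
                "n_strides must be >= 32 to allow last-30-step selection"
            )
        if not (0 < self.leg_length < 1.5):
            raise InvalidParameterError(f"implausible leg length {self.leg_length}")
        if self.subject_mass <= 0:
            raise InvalidParameterError("subject_mass must be positive")
        if not (0 <= self.stiffness_jitter < 0.5):
            raise InvalidParameterError("stiffness_jitter must lie in [0, 0.5)")
        if not (0 <= self.speed_jitter < 0.1):
            raise InvalidParameterError("speed_jitter must lie in [0, 0.1)")

    @property
    def effective_belt_scale(self) -> float:
        """Leg-length speed scaling (square root of the leg length in metres),
        mirroring the protocol's spina-malleolar belt-speed adjustment, which
        renders the dimensionless speed independent of stature."""
        if self.belt_scale is not None:
            return self.belt_scale
        return math.sqrt(self.leg_length)

    @property
    def dimensionless_speed(self) -> float:
        return (self.nominal_speed * self.effective_belt_scale
                / math.sqrt(GRAVITY * self.leg_length))


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _stance_window(u):
    """Smooth on/off ramps over the first/last 6% of stance."""
    return _smoothstep(u / 0.06) * _smoothstep((1.0 - u) / 0.06)


def _ar1_series(n, sd, rho, rng):
    """Stationary AR(1) draw of length ``n``, clipped at 2.5 standard deviations."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    white = rng.normal(0.0, sd * math.sqrt(1.0 - rho * rho), n)
    white[0] = rng.normal(0.0, sd)
    x = lfilter([1.0], [1.0, -rho], white)
    return np.clip(x, -2.5 * sd, 2.5 * sd)


def _family_jacobian(gait, v_dim, k_true, params):
    """Sensitivities of the periodic-gait observables to stiffness and speed.

    Finite differences between neighbouring fixed points of the gait family;
    a direction whose neighbouring gait cannot be solved contributes zeros
    (the per-step excursions then simply skip that direction).
    """
    fields = ("s", "tau", "F", "phi_max")
    jac = {}
    dk = max(0.05 * k_true, 0.005)
    dv = 0.005
    try:
        g_k = find_fixed_point(v_dim, k_true + dk, params, init_guess=gait.theta_star)
        jac["k"] = {f: (getattr(g_k, f) - getattr(gait, f)) / dk for f in fields}
    except Exception:
        jac["k"] = {f: 0.0 for f in fields}
    try:
        g_v = find_fixed_point(v_dim + dv, k_true, params, init_guess=gait.theta_star)
        jac["v"] = {f: (getattr(g_v, f) - getattr(gait, f)) / dv for f in fields}
    except Exception:
        jac["v"] = {f: 0.0 for f in fields}
    return jac


def generate_trial(config: SyntheticConfig):
    """Synthesize one trial; returns ``(MocapTrial, ground_truth_dict)``.

    Stride-to-stride variability is drawn *on the model's gait family*: each
    step takes a small AR(1)-correlated excursion along the
    constant-speed stiffness direction and along the speed direction, with all
    step observables (step length, period, landing speed, double-support
    duration, push-off force, torque scale) moved coherently by the family's
    sensitivities.  Raises the periodic-gait solver's error when no gait
    exists at the configured (speed, stiffness) pair.
    """
    l = config.leg_length
    t_unit = math.sqrt(l / GRAVITY)
    v_dim = config.dimensionless_speed
    params = WalkerParams(beta=config.beta, mu=config.mu_true)
    gait = find_fixed_point(v_dim, config.k_true, params)
    _, traj, _ = map_step(gait.section_state(), config.k_true, params)
    jac = _family_jacobian(gait, v_dim, config.k_true, params)

    rng = np.random.default_rng(config.seed)
    n_events = 2 * config.n_strides
    n_steps = n_events - 1

    # per-step excursions along the gait family (correlated across steps)
    dk_i = _ar1_series(n_steps, config.stiffness_jitter * config.k_true, 0.85, rng)
    dv_i = _ar1_series(n_steps, config.speed_jitter * v_dim, 0.85, rng)

    tau_model = gait.tau
    th_minus = traj.pre_collision.theta
    s_i = np.clip(gait.s + jac["k"]["s"] * dk_i + jac["v"]["s"] * dv_i,
                  0.3 * gait.s, min(1.9, 1.7 * gait.s))
    tau_i = np.clip(gait.tau + jac["k"]["tau"] * dk_i + jac["v"]["tau"] * dv_i,
                    0.5 * gait.tau, 1.5 * gait.tau)
    v_i = np.clip(v_dim + dv_i, 0.02, 0.98)
    k_i = np.maximum(config.k_true + dk_i, 0.005)
    f_i = np.maximum(gait.F + jac["k"]["F"] * dk_i + jac["v"]["F"] * dv_i,
                     0.1 * gait.F) if np.isfinite(gait.F) else np.full(n_steps, 0.0)
    th_minus_i = np.arcsin(s_i / 2.0)
    amp_i = th_minus_i / th_minus                    # arc amplitude scale
    theta_dot_minus_i = v_i / np.cos(th_minus_i)
    dt_ds_i = config.mu_true / theta_dot_minus_i     # dimensionless
    tau_i_sec = tau_i * t_unit
    dt_ds_i_sec = dt_ds_i * t_unit
    events = np.concatenate([[0.0], np.cumsum(tau_i_sec)])  # e_0 .. e_{n_events-1}

    # model single-support arcs, phase-parameterized
    ph_grid = traj.times
    theta_arc = traj.states[:, 0]
    phi_arc = traj.states[:, 1]
    s_len_i = s_i * l                                # metres, per step
    x_stance = np.concatenate([[0.0], np.cumsum(s_len_i)])[:n_steps]

    trial_tail = 0.25                                # seconds past the last event
    k_rate = config.kinematic_rate
    t_kin = np.arange(0.0, events[-1] + trial_tail, 1.0 / k_rate)
    nk = t_kin.size
    com_x = np.empty(nk)
    com_y = np.empty(nk)
    heel_x = {s: np.empty(nk) for s in SIDES}
    toe_off_x = 0.15 * l                             # toe marker ahead of heel
    hip_angle = {s: np.empty(nk) for s in SIDES}
    torque_scale = {s: np.empty(nk) for s in SIDES}

    step_of = np.clip(np.searchsorted(events, t_kin, side="right") - 1, 0, n_steps - 1)
    # double-support period of the collision at e_0 (pre-trial step, nominal)
    ds_pre_sec = dt_ds_i_sec[0]
    for i in range(n_steps):
        m = step_of == i
        if not np.any(m):
            continue
        tm = t_kin[m]
        phase = (tm - events[i]) / tau_i_sec[i] * tau_model
        th = amp_i[i] * np.interp(phase, ph_grid, theta_arc)
        ph = amp_i[i] * np.interp(phase, ph_grid, phi_arc)
        x_st = x_stance[i]                           # stance foot, ground frame
        lead = SIDES[i % 2]
        swing = SIDES[(i + 1) % 2]
        cx = x_st + l * np.sin(th)
        cy = l * np.cos(th)
        # The hybrid model changes the CoM velocity instantaneously at heel
        # strike; a human changes it over the double-support phase.  Emulate
        # the finite double support by (a) straightening the arc tail toward
        # its collision-point tangent over twice the double-support period, so
        # the CoM arrives at heel strike along the pre-collision velocity, and
        # (b) crossfading from the previous collision tangent into the new arc
        # after heel strike, delayed over the first quarter of double support
        # (the CoM keeps descending into early double support, nadir mid-DS).
        vx_end = l * v_i[i] / t_unit
        vy_end = -l * math.sin(th_minus_i[i]) * theta_dot_minus_i[i] / t_unit
        # window wide enough that the pre-event velocity-regression span of
        # the analysis (~50 ms) sits fully on the tangent plateau
        ds_tail = min(2.5 * dt_ds_i_sec[i], 0.35 * tau_i_sec[i])
        w2 = _smoothstep((tm - (events[i + 1] - ds_tail)) / (0.65 * ds_tail))
        dt_end = tm - events[i + 1]
        cx_tan = x_st + l * math.sin(th_minus_i[i]) + vx_end * dt_end
        cy_tan = l * math.cos(th_minus_i[i]) + vy_end * dt_end
        cx = (1.0 - w2) * cx + w2 * cx_tan
        cy = (1.0 - w2) * cy + w2 * cy_tan
        if i > 0:
            j = i - 1
            w = _smoothstep(((tm - events[i]) / dt_ds_i_sec[j] - 0.25) / 0.75)
            dt_loc = tm - events[i]
            vx_pre = l * v_i[j] / t_unit
            vy_pre = -l * math.sin(th_minus_i[j]) * theta_dot_minus_i[j] / t_unit
            cx_prev = x_stance[j] + l * math.sin(th_minus_i[j]) + vx_pre * dt_loc
            cy_prev = l * math.cos(th_minus_i[j]) + vy_pre * dt_loc
            com_x[m] = w * cx + (1.0 - w) * cx_prev
            com_y[m] = w * cy + (1.0 - w) * cy_prev
        else:
            com_x[m] = cx
            com_y[m] = cy
        heel_x[lead][m] = x_st
        # The trailing foot stays planted until its toe-off, then swings along
        # the model's foot path, time-warped (zero marker velocity at lift-off
        # and landing) and displacement-normalized so it lands exactly on the
        # next stance position.
        ds_start = dt_ds_i_sec[i - 1] if i > 0 else ds_pre_sec
        t_to = events[i] + ds_start
        u_sw = np.clip((tm - t_to) / max(events[i + 1] - t_to, 1e-9), 0.0, 1.0)
        p_sw = tau_model * _smoothstep(u_sw)
        th_sw = amp_i[i] * np.interp(p_sw, ph_grid, theta_arc)
        ph_sw = amp_i[i] * np.interp(p_sw, ph_grid, phi_arc)
        disp = (np.sin(th_sw) + np.sin(ph_sw)) - (
            math.sin(amp_i[i] * theta_arc[0]) + math.sin(amp_i[i] * phi_arc[0]))
        full_disp = 2.0 * math.sin(th_minus_i[i]) - (
            math.sin(amp_i[i] * theta_arc[0]) + math.sin(amp_i[i] * phi_arc[0]))
        x_prev = x_stance[i - 1] if i > 0 else x_stance[0] - s_len_i[0]
        travel = x_stance[i] + s_len_i[i] - x_prev
        heel_x[swing][m] = x_prev + travel * disp / full_disp
        hip_angle[lead][m] = th                      # stance hip, extension +
        hip_angle[swing][m] = -ph                    # swing hip, extension +
        # torque during step i reflects the previous step's stiffness draw, so
        # the quasi-stiffness window of the step record at e_i sees the same
        # draw as the record\'s geometric outcomes
        k_here = k_i[i - 1] if i > 0 else k_i[0]
        for side in SIDES:
            torque_scale[side][m] = k_here

    # treadmill frame: subtract the belt motion (average progression speed)
    belt_speed = float(np.sum(s_len_i)) / events[-1]
    com_x = com_x - belt_speed * t_kin
    for s in SIDES:
        heel_x[s] = heel_x[s] - belt_speed * t_kin
    toe_x = {s: heel_x[s] + toe_off_x for s in SIDES}

    m_g = config.subject_mass * GRAVITY
    hip_torque = {s: torque_scale[s] * hip_angle[s] * (m_g * l) for s in SIDES}

    # ---- force plates -----------------------------------------------------
    g_rate = config.grf_rate
    t_grf = np.arange(0.0, events[-1] + trial_tail, 1.0 / g_rate)
    ng = t_grf.size
    grf_y = {s: np.zeros(ng) for s in SIDES}
    grf_x = {s: np.zeros(ng) for s in SIDES}
    half_sample = 0.5 / g_rate

    def stance_profile(a0, b0, side, ds_frac, f_peak):
        sel = (t_grf > a0 + half_sample) & (t_grf < b0 - half_sample)
        if not np.any(sel):
            return
        u = (t_grf[sel] - a0) / (b0 - a0)
        w = _stance_window(u)
        humps = (np.exp(-0.5 * ((u - 0.25) / 0.16) ** 2)
                 + np.exp(-0.5 * ((u - 0.75) / 0.16) ** 2))
        grf_y[side][sel] += 1.1 * m_g * humps * w
        u_prop = 1.0 - 0.5 * ds_frac
        ap = (np.exp(-0.5 * ((u - u_prop) / 0.10) ** 2)
              - 0.8 * np.exp(-0.5 * ((u - 0.18) / 0.07) ** 2)) * w
        peak = ap.max()
        if peak > 0:
            grf_x[side][sel] += ap * (f_peak / peak)

    # leg already in stance at trial start: it is the trailing leg of the
    # double-support phase that begins at e_0 and it swings during step 0
    a0 = events[0] - tau_i_sec[0]
    b0 = events[0] + ds_pre_sec
    stance_profile(a0, b0, SIDES[1], ds_pre_sec / (b0 - a0), m_g * f_i[0])
    for i in range(n_events):
        a0 = events[i]
        j = min(i, n_steps - 1)
        if i + 1 < n_events:
            b0 = events[i + 1] + dt_ds_i_sec[j]
            ds_frac = dt_ds_i_sec[j] / (b0 - a0)
        else:
            b0 = events[-1] + tau_i_sec[-1]          # runs off the trial end
            ds_frac = dt_ds_i_sec[-1] / (b0 - a0)
        stance_profile(a0, min(b0, events[-1] + 10.0), SIDES[i % 2], ds_frac,
                       m_g * f_i[j])

    # ---- measurement noise ------------------------------------------------
    nz = config.noise
    if nz.marker > 0:
        com_x = com_x + rng.normal(0, nz.marker, nk)
        com_y = com_y + rng.normal(0, nz.marker, nk)
        for s in SIDES:
            heel_x[s] = heel_x[s] + rng.normal(0, nz.marker, nk)
            toe_x[s] = toe_x[s] + rng.normal(0, nz.marker, nk)
    if nz.angle > 0:
        for s in SIDES:
            hip_angle[s] = hip_angle[s] + rng.normal(0, nz.angle, nk)
    torque_sd = nz.torque + nz.torque_rel * (config.k_true * gait.phi_max * m_g * l)
    if torque_sd > 0:
        for s in SIDES:
            hip_torque[s] = hip_torque[s] + _ar1_series(
                nk, torque_sd / 0.99, nz.torque_ar, rng)  # clip at 2.5 sd
    if nz.grf > 0:
        for s in SIDES:
            grf_y[s] = grf_y[s] + rng.normal(0, nz.grf, ng)
            grf_x[s] = grf_x[s] + rng.normal(0, nz.grf, ng)

    trial = MocapTrial(
        kinematic_rate=k_rate, grf_rate=g_rate,
        heel_x=heel_x, toe_x=toe_x, com_x=com_x, com_y=com_y,
        hip_angle=hip_angle, hip_torque=hip_torque,
        grf_x=grf_x, grf_y=grf_y,
        subject_mass=config.subject_mass,
        belt_speed_nominal=config.nominal_speed,
        belt_scale=config.effective_belt_scale,
        subject_id=config.subject_id,
    )
    truth = {
        "config": _config_dict(config),
        "gait": gait.to_dict(),
        "k_true": config.k_true,
        "mu_true": config.mu_true,
        "s": gait.s,
        "v": gait.v,
        "b": gait.b,
        "T": gait.T,
        "F": gait.F,
        "tau": gait.tau,
        "omega": gait.omega,
        "belt_speed_actual": config.nominal_speed * config.effective_belt_scale,
        "belt_speed_frame": belt_speed,
        "per_step": {
            "hs_times": events.tolist(),
            "tau": tau_i.tolist(),
            "theta_dot_minus": theta_dot_minus_i.tolist(),
            "dt_ds": dt_ds_i.tolist(),
            "s": s_i.tolist(),
            "v": v_i.tolist(),
            "b": (s_i / 2.0 - v_i).tolist(),
            "k": k_i.tolist(),
            "F": f_i.tolist(),
        },
    }
    return trial, truth


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["noise"] = asdict(config.noise)
    return d


def generate_cohort(
    base: SyntheticConfig,
    n_subjects: int = 11,
    speed_list=NOMINAL_BELT_SPEEDS,
    k_by_speed: dict | None = None,
    k_subject_sd: float = 0.03,
    k_speed_sd: float = 0.01,
    mass_sd: float = 9.1,
    leg_sd: float = 0.05,
    seed: int | None = None,
):
    """Generate a subject x speed cohort of synthetic trials.

    Subjects receive anthropometric jitter (mass, leg length) and a persistent
    stiffness offset; per-speed stiffness is drawn around ``k_by_speed`` (by
    default the empirical progression from 0.08 at 0.50 m/s to 0.16 at
    1.75 m/s) and clipped to the admissible range at that speed.  The designed
    couplings — stiffer hips raise peak flexion torque and lower propulsion,
    margin of stability, and step length at fixed speed — come entirely from
    the walking model.

    Yields ``(config, trial, truth)`` triples.
    """
    if k_by_speed is None:
        k_by_speed = DEFAULT_K_BY_SPEED
    rng = np.random.default_rng(base.seed if seed is None else seed)
    for subj in range(n_subjects):
        mass = float(np.clip(rng.normal(base.subject_mass, mass_sd), 40.0, 95.0))
        leg = float(np.clip(rng.normal(base.leg_length, leg_sd), 0.80, 1.10))
        k_offset = rng.normal(0.0, k_subject_sd)
        for speed in speed_list:
            k_mean = k_by_speed.get(speed, base.k_true)
            k_floor = _K_FLOOR_BY_SPEED.get(speed, 0.02)
            k_true = float(np.clip(
                k_mean + k_offset + rng.normal(0.0, k_speed_sd),
                k_floor, 0.30,
            ))
            config = replace(
                base,
                k_true=k_true,
                nominal_speed=speed,
                subject_mass=mass,
                leg_length=leg,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=f"S{subj:02d}",
            )
            trial, truth = generate_trial(config)
            yield config, trial, truth
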