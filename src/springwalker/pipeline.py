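"""Treadmill gait-analysis pipeline.

Mirrors the human-gait analysis the walking model is tested against: zero-lag
low-pass filtering, ground-reaction-force gait events, per-step geometry and
margin of stability, the double-support inverse-proportionality regression, hip
quasi-stiffness from the torque-angle relation over the swing window, peak
torque and propulsive-force outcomes, and the per-speed correlation battery
with Bonferroni-adjusted significance.

All per-step quantities are nondimensionalized so they compare directly with
the model's: lengths by the reconstructed leg length ``l_expt`` (or by the
CoM-to-heel distance for the margin of stability), speeds by ``sqrt(g l)``,
periods by ``sqrt(l/g)``, torques by ``M g l``, and forces by ``M g``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dataclass_fields

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import (
    GeometryError,
    InsufficientDataError,
    InvalidParameterError,
    NoEventsError,
    RegressionError,
    SchemaError,
)

__all__ = [
    "MocapTrial",
    "GaitEvents",
    "StepWindow",
    "StepMetricsRecord",
    "RegressionResult",
    "CorrelationCell",
    "CorrelationReport",
    "TrialAnalysis",
    "zero_lag_lowpass",
    "detect_gait_events",
    "step_geometry",
    "mos_expt",
    "fit_double_support",
    "fit_quasi_stiffness",
    "step_outcomes",
    "analyze_trial",
    "correlation_analysis",
    "records_frame",
]

GRAVITY = 9.81
SIDES = ("L", "R")

#: Default cut-off frequencies (Hz) for kinematic and force channels.
KINEMATIC_CUTOFF = 6.0
GRF_CUTOFF = 18.0

#: Vertical-GRF threshold (N) from which events are traced back to zero.
EVENT_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MocapTrial:
    """One treadmill trial: time-aligned channels plus subject metadata.

    Kinematic channels are sampled at ``kinematic_rate`` (Hz), force channels
    at ``grf_rate``.  Marker and CoM positions are metres along the lab X
    (travel) and Y (vertical) axes in the treadmill frame; hip angles are
    radians with extension positive; hip torques are N·m with flexion
    positive; forces are N with the anterior (X) and upward (Y) components.
    """

    kinematic_rate: float
    grf_rate: float
    heel_x: dict
    toe_x: dict
    com_x: np.ndarray
    com_y: np.ndarray
    hip_angle: dict
    hip_torque: dict
    grf_x: dict
    grf_y: dict
    subject_mass: float
    belt_speed_nominal: float
    belt_scale: float = 1.0
    subject_id: str = "S00"

    def __post_init__(self):
        if self.kinematic_rate <= 0 or self.grf_rate <= 0:
            raise SchemaError("sampling rates must be positive")
        n = len(self.com_x)
        for name in ("heel_x", "toe_x", "hip_angle", "hip_torque"):
            ch = getattr(self, name)
            for side in SIDES:
                if side not in ch:
                    raise SchemaError(f"channel {name} missing side {side}")
                if len(ch[side]) != n:
                    raise SchemaError(f"channel {name}[{side}] length mismatch")
        if len(self.com_y) != n:
            raise SchemaError("com_y length mismatch")
        m = len(self.grf_y["L"])
        for name in ("grf_x", "grf_y"):
            ch = getattr(self, name)
            for side in SIDES:
                if len(ch[side]) != m:
                    raise SchemaError(f"channel {name}[{side}] length mismatch")

    @property
    def kinematic_times(self) -> np.ndarray:
        return np.arange(len(self.com_x)) / self.kinematic_rate

    @property
    def grf_times(self) -> np.ndarray:
        return np.arange(len(self.grf_y["L"])) / self.grf_rate


@dataclass
class GaitEvents:
    """Heel-strike and toe-off sample indices per side (force-plate grid)."""

    heel_strikes: dict
    toe_offs: dict
    grf_rate: float

    def hs_times(self, side: str) -> np.ndarray:
        return np.asarray(self.heel_strikes[side]) / self.grf_rate

    def to_times(self, side: str) -> np.ndarray:
        return np.asarray(self.toe_offs[side]) / self.grf_rate

    def merged_heel_strikes(self):
        """All heel strikes ordered in time as ``(time, side)`` pairs."""
        ev = [(t, s) for s in SIDES for t in self.hs_times(s)]
        ev.sort()
        return ev


@dataclass(frozen=True)
class StepWindow:
    """One step: a heel strike with its neighbouring events.

    The step starts at the leading leg's heel strike ``t_hs`` and ends at the
    next (contralateral) heel strike ``t_next``; ``t_prev`` is the previous
    contralateral heel strike (the step period ending at ``t_hs`` is
    ``t_hs - t_prev``) and ``t_toe_off`` is the trailing leg's toe-off that
    closes the double-support phase after ``t_hs``.
    """

    index: int
    lead_side: str
    trail_side: str
    t_prev: float
    t_hs: float
    t_next: float
    t_toe_off: float


@dataclass
class StepMetricsRecord:
    """Per-step outcomes, all dimensionless unless noted."""

    subject_id: str
    speed_label: float
    step_index: int
    lead_side: str
    l_c_h: float        # CoM-to-leading-heel distance at heel strike, m
    x_expt: float
    xi_expt: float
    u_expt: float
    b_expt: float
    l_expt: float       # reconstructed leg length, m
    s_expt: float
    v_expt: float
    v_y: float
    theta_minus_expt: float
    theta_dot_minus_expt: float
    dt_ds_expt: float
    k_expt: float
    r2_k: float
    T_expt: float
    F_expt: float
    tau_expt: float


def records_frame(records) -> pd.DataFrame:
    cols = [f.name for f in dataclass_fields(StepMetricsRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records],
                        columns=cols)


@dataclass(frozen=True)
class RegressionResult:
    """No-intercept inverse-proportionality fit of the double-support law."""

    mu_expt: float
    r2: float
    n: int


@dataclass(frozen=True)
class CorrelationCell:
    speed_label: object
    outcome: str
    method: str | None
    r: float
    p: float
    n: int
    significant: bool


@dataclass
class CorrelationReport:
    """Per-speed correlation battery plus the pooled stiffness-cadence test."""

    cells: list
    pooled: CorrelationCell
    alpha: float
    alpha_prime: float
    report_level: float
    n_tests: int

    def cell(self, speed_label, outcome) -> CorrelationCell:
        for c in self.cells:
            if c.speed_label == speed_label and c.outcome == outcome:
                return c
        raise KeyError((speed_label, outcome))

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_prime": self.alpha_prime,
            "report_level": self.report_level,
            "n_tests": self.n_tests,
            "cells": [vars(c) for c in self.cells],
            "pooled": vars(self.pooled),
        }


@dataclass
class TrialAnalysis:
    records: list
    events: GaitEvents
    regression: RegressionResult | None

    def frame(self) -> pd.DataFrame:
        return records_frame(self.records)


# ---------------------------------------------------------------------------
# Signal processing and events
# ---------------------------------------------------------------------------

def zero_lag_lowpass(x, rate: float, cutoff: float) -> np.ndarray:
    """Fourth-order zero-lag Butterworth low-pass (forward-backward pass).

    A second-order Butterworth applied forward and backward, giving a
    fourth-order magnitude response with exactly zero phase lag.
    """
    if cutoff >= rate / 2.0:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {rate / 2} Hz"
        )
    if cutoff <= 0:
        raise InvalidParameterError(f"cutoff must be positive, got {cutoff}")
    b, a = sp_signal.butter(2, cutoff, btype="low", fs=rate)
    return sp_signal.filtfilt(b, a, np.asarray(x, dtype=float))


def _detect_side(grf, threshold, floor):
    above = grf > threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    falling = np.flatnonzero(~above[1:] & above[:-1]) + 1
    heel_strikes = []
    for i in rising:
        j = i
        while j > 0 and grf[j - 1] > floor:
            j -= 1
        hs = j - 1 if j > 0 else None  # last sample at/below the floor
        if hs is not None and (not heel_strikes or hs != heel_strikes[-1]):
            heel_strikes.append(hs)
    toe_offs = []
    n = len(grf)
    for i in falling:
        j = i
        while j < n and grf[j] > floor:
            j += 1
        if j < n and (not toe_offs or j != toe_offs[-1]):
            toe_offs.append(j)
    return np.asarray(heel_strikes, dtype=int), np.asarray(toe_offs, dtype=int)


def detect_gait_events(
    grf_y: dict,
    grf_rate: float,
    threshold: float = EVENT_THRESHOLD,
    floor: float = 0.0,
) -> GaitEvents:
    """Gait events from the vertical ground reaction force.

    Heel strike: for every up-crossing of the ``threshold`` (10 N), scan
    backward to the last sample at or below the ``floor`` (0 N by default).
    Toe-off: for every down-crossing, scan forward to the first sample at or
    below the floor.  The 10 N threshold provides hysteresis against noise
    around the floor.
    """
    heel_strikes, toe_offs = {}, {}
    for side in SIDES:
        hs, to = _detect_side(np.asarray(grf_y[side], dtype=float), threshold, floor)
        if hs.size == 0 and to.size == 0:
            raise NoEventsError(f"no {threshold} N crossings on side {side}")
        heel_strikes[side], toe_offs[side] = hs, to
    ev = GaitEvents(heel_strikes=heel_strikes, toe_offs=toe_offs, grf_rate=grf_rate)
    merged = ev.merged_heel_strikes()
    if any(a[1] == b[1] for a, b in zip(merged, merged[1:])):
        warnings.warn("heel strikes do not alternate between sides", stacklevel=2)
    return ev


def step_windows(events: GaitEvents) -> list:
    """Assemble :class:`StepWindow` objects from detected events."""
    merged = events.merged_heel_strikes()
    windows = []
    for j in range(1, len(merged) - 1):
        t_prev, prev_side = merged[j - 1]
        t_hs, lead = merged[j]
        t_next, next_side = merged[j + 1]
        trail = "L" if lead == "R" else "R"
        if prev_side != trail or next_side != trail:
            continue  # malformed (non-alternating) neighbourhood
        to_times = events.to_times(trail)
        after = to_times[(to_times > t_hs) & (to_times < t_next)]
        if after.size == 0:
            continue
        windows.append(StepWindow(
            index=j, lead_side=lead, trail_side=trail,
            t_prev=t_prev, t_hs=t_hs, t_next=t_next, t_toe_off=float(after[0]),
        ))
    return windows


# ---------------------------------------------------------------------------
# Per-step metrics
# ---------------------------------------------------------------------------

def _interp_at(times, x, t):
    return float(np.interp(t, times, x))


def _pre_event_velocity(x, rate: float, t_event: float,
                        window: float = 0.05) -> float:
    """Velocity just before an event: least-squares slope over a short window.

    The slope is fit over the last ``window`` seconds of samples strictly
    before the event.  Sampling only pre-event frames keeps the estimate on
    the pre-collision arc (the CoM vertical velocity reverses around heel
    strike), and the short regression averages out marker noise that a
    two-point difference would amplify.  The channel should be unfiltered: a
    zero-lag low-pass is non-causal and would leak post-collision motion into
    the pre-collision estimate.
    """
    f_end = int(math.ceil(t_event * rate)) - 1
    n = max(int(round(window * rate)), 3)
    f_start = f_end - n + 1
    f_start = max(f_start, 0)
    f_end = min(f_end, len(x) - 1)
    if f_end - f_start < 2:
        raise GeometryError("too few frames before event for a velocity estimate")
    idx = np.arange(f_start, f_end + 1)
    slope, _ = np.polyfit(idx / rate, np.asarray(x[f_start:f_end + 1], dtype=float), 1)
    return float(slope)


def step_geometry(trial: MocapTrial, events: GaitEvents, step: StepWindow,
                  velocity_source: MocapTrial | None = None) -> dict:
    """Step geometry and the model-matched state at heel strike.

    The human posture at heel strike is reduced to the compass model: the CoM
    vertical projection is assumed to bisect the step, so the effective leg
    length follows from Pythagoras, ``l_expt = sqrt(h_com^2 + (L/2)^2)`` with
    ``L`` the heel-to-heel distance.  The forward CoM velocity is
    belt-corrected by subtracting the trailing toe-marker velocity.
    """
    t = trial.kinematic_times
    rate = trial.kinematic_rate
    th = step.t_hs
    heel_lead = _interp_at(t, trial.heel_x[step.lead_side], th)
    heel_trail = _interp_at(t, trial.heel_x[step.trail_side], th)
    com_y_hs = _interp_at(t, trial.com_y, th)
    step_len = heel_lead - heel_trail
    if step_len <= 0:
        raise GeometryError(f"non-positive step length {step_len:.4f} m")
    l_expt = math.hypot(com_y_hs, step_len / 2.0)
    s_expt = step_len / l_expt
    if s_expt / 2.0 > 1.0:
        raise GeometryError(f"step length {step_len} exceeds twice the leg length")
    vs = velocity_source if velocity_source is not None else trial
    com_xdot = _pre_event_velocity(vs.com_x, rate, th)
    toe_xdot = _pre_event_velocity(vs.toe_x[step.trail_side], rate, th)
    com_ydot = _pre_event_velocity(vs.com_y, rate, th)
    v_scale = math.sqrt(GRAVITY * l_expt)
    v_expt = (com_xdot - toe_xdot) / v_scale
    v_y = com_ydot / v_scale
    theta_minus = math.asin(s_expt / 2.0)
    theta_dot_minus = v_expt * math.cos(theta_minus) - v_y * math.sin(theta_minus)
    t_unit = math.sqrt(l_expt / GRAVITY)
    return {
        "l_expt": l_expt,
        "s_expt": s_expt,
        "v_expt": v_expt,
        "v_y": v_y,
        "theta_minus_expt": theta_minus,
        "theta_dot_minus_expt": theta_dot_minus,
        "tau_expt": (step.t_hs - step.t_prev) / t_unit,
        "dt_ds_expt": (step.t_toe_off - step.t_hs) / t_unit,
    }


def mos_expt(trial: MocapTrial, events: GaitEvents, step: StepWindow,
             velocity_source: MocapTrial | None = None) -> dict:
    """Margin of stability at heel strike from the extrapolated centre of mass.

    Positions are nondimensionalized by the CoM-to-leading-heel distance
    ``l_c_h`` and the belt-corrected CoM velocity by ``sqrt(g l_c_h)``; the
    margin ``b = u - xi`` is independent of the lab origin.
    """
    t = trial.kinematic_times
    rate = trial.kinematic_rate
    th = step.t_hs
    heel_lead = _interp_at(t, trial.heel_x[step.lead_side], th)
    com_x_hs = _interp_at(t, trial.com_x, th)
    com_y_hs = _interp_at(t, trial.com_y, th)
    l_c_h = math.hypot(heel_lead - com_x_hs, com_y_hs)
    if l_c_h <= 0:
        raise GeometryError("zero CoM-to-heel distance")
    vs = velocity_source if velocity_source is not None else trial
    com_xdot = _pre_event_velocity(vs.com_x, rate, th)
    toe_xdot = _pre_event_velocity(vs.toe_x[step.trail_side], rate, th)
    u = heel_lead / l_c_h
    x = com_x_hs / l_c_h
    xdot = (com_xdot - toe_xdot) / math.sqrt(GRAVITY * l_c_h)
    xi = x + xdot
    return {"l_c_h": l_c_h, "x_expt": x, "xi_expt": xi, "u_expt": u,
            "b_expt": u - xi}


def fit_quasi_stiffness(
    hip_angle: np.ndarray,
    hip_torque_nd: np.ndarray,
    rate: float,
    step: StepWindow,
    min_frames: int = 10,
) -> tuple[float, float]:
    """Hip quasi-stiffness over the swing-related window.

    The window runs from the frame of maximum hip extension during pre-swing
    (contralateral heel strike to ipsilateral toe-off) to the end of the swing
    phase (one frame before the next ipsilateral heel strike).  The
    quasi-stiffness is the magnitude of the ordinary-least-squares slope of the
    (flexion-positive, pre-nondimensionalized) torque on the
    (extension-positive) angle; with these conventions a restoring spring has
    positive slope.
    """
    f_hs = int(round(step.t_hs * rate))
    f_to = int(round(step.t_toe_off * rate))
    f_end = int(math.ceil(step.t_next * rate))  # one frame before next HS
    f_to = max(f_to, f_hs + 1)
    peak = f_hs + int(np.argmax(hip_angle[f_hs:f_to + 1]))
    a = hip_angle[peak:f_end]
    q = hip_torque_nd[peak:f_end]
    if len(a) < min_frames:
        raise InsufficientDataError(
            f"quasi-stiffness window has {len(a)} frames (< {min_frames})"
        )
    if np.ptp(a) == 0:
        raise RegressionError("degenerate hip-angle window (constant angle)")
    slope, intercept = np.polyfit(a, q, 1)
    resid = q - (slope * a + intercept)
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    return abs(float(slope)), r2


def step_outcomes(trial: MocapTrial, events: GaitEvents, step: StepWindow,
                  grf_x_filtered: dict | None = None) -> dict:
    """Peak hip flexion torque and propulsive force of the swinging leg.

    Maxima are taken over the swinging (trailing) leg's gait cycle — from its
    previous heel strike to one frame before its next one — and
    nondimensionalized by ``M g l_expt`` (torque) and ``M g`` (force).
    """
    geo = step_geometry(trial, events, step)
    m_g = trial.subject_mass * GRAVITY
    side = step.trail_side
    k_rate = trial.kinematic_rate
    f0 = int(round(step.t_prev * k_rate))
    f1 = int(math.ceil(step.t_next * k_rate))
    torque = trial.hip_torque[side][f0:f1]
    if torque.size == 0:
        raise SchemaError("empty torque window")
    grf_x = (grf_x_filtered or trial.grf_x)[side]
    g0 = int(round(step.t_prev * trial.grf_rate))
    g1 = int(math.ceil(step.t_next * trial.grf_rate))
    fx = grf_x[g0:g1]
    if fx.size == 0:
        raise SchemaError("empty anterior-GRF window")
    return {
        "T_expt": float(np.max(torque)) / (m_g * geo["l_expt"]),
        "F_expt": float(np.max(fx)) / m_g,
    }


# ---------------------------------------------------------------------------
# Regressions and correlations
# ---------------------------------------------------------------------------

def fit_double_support(dt_ds, theta_dot_minus, min_steps: int = 10) -> RegressionResult:
    """No-intercept fit of the double-support law ``theta_dot- = mu / dt_ds``.

    Ordinary least squares of the pre-collision angular speed on the
    reciprocal double-support period, without intercept; the coefficient of
    determination uses the conventional total sum of squares about the mean.
    """
    dt = np.asarray(dt_ds, dtype=float)
    y = np.asarray(theta_dot_minus, dtype=float)
    if dt.size != y.size:
        raise RegressionError("dt_ds and theta_dot_minus must have equal length")
    if dt.size < min_steps:
        raise InsufficientDataError(
            f"double-support regression needs >= {min_steps} steps, got {dt.size}"
        )
    if np.any(dt <= 0):
        raise RegressionError("double-support periods must be positive")
    x = 1.0 / dt
    mu = float(x @ y / (x @ x))
    ss_res = float(np.sum((y - mu * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        if ss_res > 1e-20 * y.size:
            raise RegressionError("degenerate variance in theta_dot_minus")
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return RegressionResult(mu_expt=mu, r2=r2, n=int(dt.size))


def _route_correlation(x, y, normality_alpha=0.05):
    """Pearson when both samples pass Shapiro-Wilk normality, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal = all(
            sp_stats.shapiro(v).pvalue > normality_alpha
            for v in (x, y)
            if np.ptp(v) > 0
        ) and np.ptp(x) > 0 and np.ptp(y) > 0
        if normal:
            res = sp_stats.pearsonr(x, y)
            return "pearson", float(res.statistic), float(res.pvalue)
        res = sp_stats.spearmanr(x, y)
    return "spearman", float(res.statistic), float(res.pvalue)


def correlation_analysis(
    records: pd.DataFrame,
    alpha: float = 0.05,
    n_tests: int = 4,
    min_n: int = 3,
) -> CorrelationReport:
    """Per-speed correlations of hip quasi-stiffness with the gait outcomes.

    For each belt speed the quasi-stiffness ``k_expt`` is correlated with the
    peak flexion torque, propulsive force, margin of stability, and step
    length; one pooled correlation of ``k_expt`` with the step frequency
    ``1/tau_expt`` spans all speeds.  Pearson's coefficient is used when both
    variables pass Shapiro-Wilk normality at 0.05, Spearman's otherwise.  The
    per-speed significance level is Bonferroni-adjusted,
    ``alpha' = 1 - (1-alpha)^(1/n_tests)``, applied at its rounded (2-decimal)
    reporting level.
    """
    if isinstance(records, (list, tuple)):
        records = records_frame(records)
    alpha_prime = 1.0 - (1.0 - alpha) ** (1.0 / n_tests)
    report_level = round(alpha_prime, 2)
    outcomes = ("T_expt", "F_expt", "b_expt", "s_expt")
    cells = []
    for speed, grp in records.groupby("speed_label", sort=True):
        for outcome in outcomes:
            sub = grp[["k_expt", outcome]].dropna()
            if len(sub) < min_n:
                cells.append(CorrelationCell(
                    speed_label=speed, outcome=outcome, method=None,
                    r=math.nan, p=math.nan, n=len(sub), significant=False,
                ))
                continue
            method, r, p = _route_correlation(sub["k_expt"], sub[outcome])
            cells.append(CorrelationCell(
                speed_label=speed, outcome=outcome, method=method,
                r=r, p=p, n=len(sub), significant=bool(p < report_level),
            ))
    pooled_sub = records[["k_expt", "tau_expt"]].dropna()
    if len(pooled_sub) < min_n:
        pooled = CorrelationCell(
            speed_label="all", outcome="inv_tau_expt", method=None,
            r=math.nan, p=math.nan, n=len(pooled_sub), significant=False,
        )
    else:
        method, r, p = _route_correlation(
            pooled_sub["k_expt"], 1.0 / pooled_sub["tau_expt"]
        )
        pooled = CorrelationCell(
            speed_label="all", outcome="inv_tau_expt", method=method,
            r=r, p=p, n=len(pooled_sub), significant=bool(p < alpha),
        )
    return CorrelationReport(
        cells=cells, pooled=pooled, alpha=alpha, alpha_prime=alpha_prime,
        report_level=report_level, n_tests=n_tests,
    )


# ---------------------------------------------------------------------------
# Trial-level driver
# ---------------------------------------------------------------------------

def analyze_trial(
    trial: MocapTrial,
    n_steps: int = 30,
    filter_signals: bool = True,
    detect_on_filtered: bool = False,
    floor: float = 0.0,
) -> TrialAnalysis:
    """Run the full per-trial analysis and keep the last ``n_steps`` steps.

    Channels are low-pass filtered first (6 Hz kinematics, 18 Hz forces); gait
    events are detected on the raw vertical GRF by default, because the
    zero-lag filter is non-causal and smears the contact onsets that the 0 N
    crossing rule relies on.  For the same reason the at-heel-strike velocity
    estimates are fit on the unfiltered kinematics (a short pre-event
    least-squares slope).  Steps from both sides are pooled.
    """
    raw_trial = trial
    if filter_signals:
        kr, gr = trial.kinematic_rate, trial.grf_rate
        f = lambda x, r, c: zero_lag_lowpass(x, r, c)
        trial = MocapTrial(
            kinematic_rate=kr, grf_rate=gr,
            heel_x={s: f(trial.heel_x[s], kr, KINEMATIC_CUTOFF) for s in SIDES},
            toe_x={s: f(trial.toe_x[s], kr, KINEMATIC_CUTOFF) for s in SIDES},
            com_x=f(trial.com_x, kr, KINEMATIC_CUTOFF),
            com_y=f(trial.com_y, kr, KINEMATIC_CUTOFF),
            hip_angle={s: f(trial.hip_angle[s], kr, KINEMATIC_CUTOFF) for s in SIDES},
            hip_torque={s: f(trial.hip_torque[s], kr, KINEMATIC_CUTOFF) for s in SIDES},
            grf_x={s: f(trial.grf_x[s], gr, GRF_CUTOFF) for s in SIDES},
            grf_y={s: trial.grf_y[s] if not detect_on_filtered
                   else f(trial.grf_y[s], gr, GRF_CUTOFF) for s in SIDES},
            subject_mass=trial.subject_mass,
            belt_speed_nominal=trial.belt_speed_nominal,
            belt_scale=trial.belt_scale,
            subject_id=trial.subject_id,
        )
    events = detect_gait_events(trial.grf_y, trial.grf_rate, floor=floor)
    windows = step_windows(events)
    if not windows:
        raise NoEventsError("no complete step windows in trial")
    windows = windows[-n_steps:]
    records = []
    m_g_l = trial.subject_mass * GRAVITY  # torque scale completed per step
    for w in windows:
        try:
            geo = step_geometry(trial, events, w, velocity_source=raw_trial)
            mos = mos_expt(trial, events, w, velocity_source=raw_trial)
            torque_nd = trial.hip_torque[w.trail_side] / (m_g_l * geo["l_expt"])
            k_expt, r2_k = fit_quasi_stiffness(
                trial.hip_angle[w.trail_side], torque_nd,
                trial.kinematic_rate, w,
            )
            out = step_outcomes(trial, events, w)
        except (GeometryError, InsufficientDataError, RegressionError) as err:
            warnings.warn(f"step {w.index} skipped: {err}", stacklevel=2)
            continue
        records.append(StepMetricsRecord(
            subject_id=trial.subject_id,
            speed_label=trial.belt_speed_nominal,
            step_index=w.index,
            lead_side=w.lead_side,
            k_expt=k_expt,
            r2_k=r2_k,
            **geo, **mos, **out,
        ))
    regression = None
    if len(records) >= 10:
        regression = fit_double_support(
            [r.dt_ds_expt for r in records],
            [r.theta_dot_minus_expt for r in records],
        )
    return TrialAnalysis(records=records, events=events, regression=regression)
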