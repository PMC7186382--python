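"""Forward simulation of the neuro-musculoskeletal arm.

The coupled system integrated here has one mechanical degree of freedom
(elbow angle and velocity) plus two states per muscle (activity and fiber
length).  Muscle-path geometry is sampled from precomputed spline tables;
the fiber velocity is resolved algebraically inside the right-hand side
from the internal force balance of each muscle-tendon unit.

Feedback introduces a constant time delay, making the system a delay
differential equation.  It is integrated by the method of steps: the
horizon is split into segments no longer than the delay, each solved with
a stiff variable-step solver with dense output; the stored dense solutions
serve as the history buffer for the delayed terms of later segments.
Piecewise-constant stimulation switches and the torque-impulse window are
breakpoints between segments; the impulse onset (first crossing of the
configured traversed-angle fraction) is located by integrator event
detection and latched.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .config import FeedbackConfig, ModelConfig, TorqueModelConfig
from .controller import (ReferenceTrajectory, TriphasicPattern, closed_loop_u,
                         open_loop_u, total_u)
from .mtu import (activation_rate, fiber_velocity, isometric_equilibrium,
                  see_force)
from .planner import MovementPlan, desired_trajectory
from .plant import (ArmState, ImpulseScheduler, PerturbationSpec, RangeError,
                    equations_of_motion, NO_PERTURBATION)
from .routing import RoutingTables

logger = logging.getLogger(__name__)

__all__ = ["ModelContext", "SimResult", "TorqueSimResult",
           "equilibrium_initial_state", "simulate_muscle_model",
           "simulate_torque_model"]


class ModelContext:
    """Config plus the precomputed routing tables and parameter arrays."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        geom = cfg.geometry
        self.tables = RoutingTables(
            [m.path for m in cfg.muscles], geom.upper_arm_length,
            (geom.phi_min, geom.phi_max))
        self.params = [m.params for m in cfg.muscles]
        self.l_opt = np.array([p.l_ce_opt for p in self.params])
        self.n_muscles = len(self.params)


@dataclass
class SimResult:
    """Densely sampled time series of one simulation run (SI units)."""

    t: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    u_open: np.ndarray        # (n, m)
    u_closed: np.ndarray
    u_total: np.ndarray
    activity: np.ndarray
    l_ce: np.ndarray
    v_ce: np.ndarray
    force: np.ndarray
    contact_first: np.ndarray     # (n, m) resultant at first deflection ellipse
    constraint_force: np.ndarray  # (n, 2)
    active_torque: np.ndarray
    impulse_onset: float | None = None
    impulse_offset: float | None = None
    meta: dict = field(default_factory=dict)
    # dense in-memory fiber state (l_ce, v_ce) of this run; backs the exact
    # feedback reference, not serialized
    fiber_state_fn: object | None = None


@dataclass
class TorqueSimResult:
    t: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    torque: np.ndarray
    impulse_onset: float | None = None
    impulse_offset: float | None = None
    meta: dict = field(default_factory=dict)


class _History:
    """Piecewise dense solution; constant initial state before start."""

    def __init__(self, t0: float, y0: np.ndarray):
        self.t0 = t0
        self.y0 = np.asarray(y0, dtype=float)
        self.ends: list[float] = []
        self.sols: list = []

    def add(self, sol) -> None:
        self.ends.append(float(sol.t_max))
        self.sols.append(sol)

    def state(self, s: float) -> np.ndarray:
        if not self.sols or s <= self.sols[0].t_min:
            return self.y0
        i = bisect.bisect_left(self.ends, s)
        if i >= len(self.sols):
            if s <= self.ends[-1] + 1e-9:
                i = len(self.sols) - 1
            else:
                raise RuntimeError(f"history underrun at t={s:.6f}")
        return self.sols[i](s)

    def sample(self, ts: np.ndarray) -> np.ndarray:
        return np.column_stack([self.state(t) for t in ts])


def equilibrium_initial_state(ctx: ModelContext, u0: np.ndarray,
                              phi0: float) -> np.ndarray:
    """ODE initial state consistent with a static equilibrium start."""
    lengths = ctx.tables.lengths(phi0)
    l_ce = np.empty(ctx.n_muscles)
    act = np.empty(ctx.n_muscles)
    for i, p in enumerate(ctx.params):
        l_ce[i], act[i], _ = isometric_equilibrium(float(u0[i]),
                                                   float(lengths[i]), p)
    return np.concatenate([[phi0, 0.0], act, l_ce])


def _segment_plan(breaks, horizon, chunk):
    """Sorted segment boundaries: explicit breakpoints + delay chunking."""
    pts = sorted({0.0, horizon} | {b for b in breaks if 0.0 < b < horizon})
    if chunk is None or not np.isfinite(chunk):
        return pts
    out = [pts[0]]
    for b in pts[1:]:
        a = out[-1]
        n_sub = int(np.ceil((b - a) / chunk - 1e-12))
        for k in range(1, n_sub):
            out.append(a + (b - a) * k / n_sub)
        out.append(b)
    return out


def _run_segments(rhs, y0, horizon, breaks, chunk, scheduler, cfg, history,
                  impulse_duration=0.0375):
    """Integrate through the segment plan, locating the impulse onset.

    Appends the dense per-segment solutions to ``history`` as integration
    proceeds, so delayed terms in ``rhs`` may read it (segments are no
    longer than the delay, hence delayed lookups stay in completed
    segments).
    """
    geom = cfg.geometry
    solver = cfg.solver
    t_cur, y_cur = 0.0, np.asarray(y0, dtype=float)

    def guard_hi(t, y):
        return y[0] - geom.phi_max
    guard_hi.terminal, guard_hi.direction = True, 1.0

    def guard_lo(t, y):
        return y[0] - geom.phi_min
    guard_lo.terminal, guard_lo.direction = True, -1.0

    pending_breaks = list(breaks)

    while t_cur < horizon - 1e-12:
        seg = _segment_plan(pending_breaks, horizon, chunk)
        nxt = next(b for b in seg if b > t_cur + 1e-12)
        events = [guard_hi, guard_lo]
        watch_impulse = scheduler is not None and scheduler.onset_time is None
        if watch_impulse:
            def impulse_event(t, y, _s=scheduler):
                return _s.onset_event(t, y[0])
            impulse_event.terminal, impulse_event.direction = True, 1.0
            events.append(impulse_event)
        sol = solve_ivp(rhs, (t_cur, nxt), y_cur, method=solver.method,
                        rtol=solver.rtol, atol=solver.atol,
                        dense_output=True, events=events)
        if not sol.success:
            raise RuntimeError(f"integration failed at t={t_cur:.3f}: "
                               f"{sol.message}")
        if sol.t_events[0].size or sol.t_events[1].size:
            raise RangeError(
                f"elbow angle left the anatomical range near t="
                f"{float(sol.t[-1]):.3f} s")
        history.add(sol.sol)
        t_cur = float(sol.t[-1])
        y_cur = sol.y[:, -1].copy()
        if watch_impulse and sol.t_events[2].size:
            t_star = float(sol.t_events[2][0])
            scheduler.latch(t_star)
            pending_breaks += [t_star, t_star + impulse_duration]
    if scheduler is not None:
        scheduler.warn_if_never_fired()
    return history


# --------------------------------------------------------------------------
# musculoskeletal model
# --------------------------------------------------------------------------

def simulate_muscle_model(ctx: ModelContext, pattern: TriphasicPattern,
                          feedback: FeedbackConfig | None = None,
                          reference: ReferenceTrajectory | None = None,
                          pert: PerturbationSpec = NO_PERTURBATION,
                          horizon: float = 1.0,
                          meta: dict | None = None,
                          record_for_delay: float | None = None) -> SimResult:
    """Run one trial of the muscle-driven arm and sample it densely.

    ``record_for_delay`` segments an open-loop recording run exactly like a
    closed-loop run with that feedback delay, so that a later replay with
    the recorded reference integrates an identical segment plan and the
    feedback signal cancels exactly.
    """
    cfg = ctx.cfg
    m = ctx.n_muscles
    fb = feedback if feedback is not None else FeedbackConfig(enabled=False)
    fb_active = (fb.enabled and (fb.k_p > 0 or fb.k_d > 0)
                 and reference is not None)
    if fb_active and fb.delay <= 0:
        raise ValueError("feedback with zero delay is not supported")

    y0 = equilibrium_initial_state(ctx, pattern.u0, _start_angle(pattern, ctx))
    history = _History(0.0, y0)   # filled during integration; read by feedback

    def fiber_state_at(s):
        y = history.state(s)
        phi, omega = y[0], y[1]
        act = y[2:2 + m]
        l_ce = y[2 + m:]
        arms = ctx.tables.moment_arms(phi)
        lengths = ctx.tables.lengths(phi)
        v_ce = np.array([
            fiber_velocity(float(l_ce[i]), float(act[i]), float(lengths[i]),
                           float(-arms[i] * omega), ctx.params[i])
            for i in range(m)])
        return l_ce, v_ce

    scheduler = None
    if pert.kind.value == "torque_impulse":
        start = _start_angle(pattern, ctx)
        end = _end_angle(pattern, ctx, start)
        scheduler = ImpulseScheduler(pert, start, end)
        if scheduler.threshold <= 0:
            scheduler.latch(pattern.movement_onset)

    def u_closed_at(t):
        if not fb_active:
            return np.zeros(m)
        return closed_loop_u(t, fiber_state_at, reference, fb, ctx.l_opt)

    def rhs(t, y):
        phi, omega = y[0], y[1]
        act = y[2:2 + m]
        l_ce = y[2 + m:]
        arms = ctx.tables.moment_arms(phi)
        lengths = ctx.tables.lengths(phi)
        u = total_u(open_loop_u(t, pattern), u_closed_at(t))
        dact = np.empty(m)
        dlce = np.empty(m)
        tau = 0.0
        for i, p in enumerate(ctx.params):
            dact[i] = activation_rate(float(act[i]), float(u[i]),
                                      float(l_ce[i]), p)
            v_mtu = -arms[i] * omega
            v = fiber_velocity(float(l_ce[i]), float(act[i]),
                               float(lengths[i]), float(v_mtu), p)
            dlce[i] = v
            force = see_force(float(lengths[i] - l_ce[i]), p) \
                + p.serial_damping * (v_mtu - v)
            tau += arms[i] * max(force, 0.0)
        active = scheduler.active(t) if scheduler is not None else False
        alpha = equations_of_motion(ArmState(phi, omega), tau, cfg.geometry,
                                    pert, active)
        return np.concatenate([[omega, alpha], dact, dlce])

    chunk = fb.delay if fb_active else record_for_delay
    _run_segments(rhs, y0, horizon, list(pattern.breakpoints),
                  chunk, scheduler, cfg, history,
                  impulse_duration=pert.impulse_duration)
    result = _sample_muscle_result(ctx, history, pattern, fb, fb_active,
                                   u_closed_at, pert, scheduler, horizon,
                                   meta or {})
    result.fiber_state_fn = fiber_state_at
    return result


def _start_angle(pattern, ctx):
    # the initial posture is implicit in u0; the caller records it in meta,
    # but for impulse scheduling and initial conditions we carry it on the
    # pattern via an attribute set by the calibration stage.
    return pattern.__dict__.get("_start_angle", ctx.cfg.case.start_angle_deg * np.pi / 180)


def _end_angle(pattern, ctx, start):
    return pattern.__dict__.get("_end_angle", ctx.cfg.case.end_angle_deg * np.pi / 180)


def attach_posture(pattern: TriphasicPattern, start_angle: float,
                   end_angle: float) -> TriphasicPattern:
    """Record the start/end posture (rad) on a pattern instance."""
    object.__setattr__(pattern, "_start_angle", float(start_angle))
    object.__setattr__(pattern, "_end_angle", float(end_angle))
    return pattern


def _sample_muscle_result(ctx, history, pattern, fb, fb_active, u_closed_at,
                          pert, scheduler, horizon, meta) -> SimResult:
    cfg = ctx.cfg
    m = ctx.n_muscles
    dt = cfg.solver.output_dt
    t = np.arange(0.0, horizon + dt / 2, dt)
    Y = history.sample(t)
    phi, omega = Y[0], Y[1]
    act = Y[2:2 + m].T
    l_ce = Y[2 + m:].T

    u_open = np.array([open_loop_u(tk, pattern) for tk in t])
    u_closed = np.array([u_closed_at(tk) for tk in t])
    u_tot = total_u(u_open, u_closed)

    v_ce = np.empty((len(t), m))
    force = np.empty((len(t), m))
    contact = np.empty((len(t), m))
    torque = np.empty(len(t))
    constraint = np.empty((len(t), 2))
    geom = cfg.geometry
    for k, tk in enumerate(t):
        arms = ctx.tables.moment_arms(phi[k])
        lengths = ctx.tables.lengths(phi[k])
        hvec = ctx.tables.forearm_force_units(phi[k])
        tau = 0.0
        fnet = np.zeros(2)
        for i, p in enumerate(ctx.params):
            v_mtu = -arms[i] * omega[k]
            v = fiber_velocity(float(l_ce[k, i]), float(act[k, i]),
                               float(lengths[i]), float(v_mtu), p)
            v_ce[k, i] = v
            f = see_force(float(lengths[i] - l_ce[k, i]), p) \
                + p.serial_damping * (v_mtu - v)
            f = max(f, 0.0)
            force[k, i] = f
            tau += arms[i] * f
            fnet += f * hvec[i]
            cunits = ctx.tables.contact_force_units(phi[k], i)
            contact[k, i] = f * np.linalg.norm(cunits[0]) if cunits else 0.0
        torque[k] = tau
        active = scheduler.active(tk) if scheduler is not None else False
        alpha = equations_of_motion(ArmState(phi[k], omega[k]), tau,
                                    geom, pert, active)
        # forearm COM acceleration for the Newton-Euler constraint balance
        c, s = np.cos(phi[k]), np.sin(phi[k])
        fhat = np.array([c, s])
        ghat = np.array([-s, c])
        a_com = geom.forearm_com_distance * (alpha * ghat - omega[k] ** 2 * fhat)
        constraint[k] = geom.forearm_mass * a_com - fnet

    return SimResult(
        t=t, phi=phi, omega=omega, u_open=u_open, u_closed=u_closed,
        u_total=u_tot, activity=act, l_ce=l_ce, v_ce=v_ce, force=force,
        contact_first=contact, constraint_force=constraint,
        active_torque=torque,
        impulse_onset=None if scheduler is None else scheduler.onset_time,
        impulse_offset=None if scheduler is None else scheduler.offset_time,
        meta=meta)


# --------------------------------------------------------------------------
# torque-driven comparison model
# --------------------------------------------------------------------------

def simulate_torque_model(ctx: ModelContext, recorded_torque,
                          plan: MovementPlan,
                          tm: TorqueModelConfig,
                          feedback_on: bool,
                          pert: PerturbationSpec = NO_PERTURBATION,
                          horizon: float = 1.0,
                          meta: dict | None = None) -> TorqueSimResult:
    """Idealized torque-driven arm replaying the recorded net muscle torque.

    Same plant parameters as the musculoskeletal model; actuation is the
    net active joint torque recorded from its unperturbed movement, plus
    (when ``feedback_on``) a delayed PD torque on the joint-angle error
    relative to the minimum-jerk desired trajectory.
    """
    cfg = ctx.cfg
    if isinstance(recorded_torque, SimResult):
        recorded_torque = CubicSpline(recorded_torque.t,
                                      recorded_torque.active_torque)
    phi0, _, _ = desired_trajectory(0.0, plan)
    y0 = np.array([phi0, 0.0])

    scheduler = None
    if pert.kind.value == "torque_impulse":
        scheduler = ImpulseScheduler(pert, plan.start_angle, plan.end_angle)
        if scheduler.threshold <= 0:
            scheduler.latch(plan.movement_onset)

    history = _History(0.0, y0)

    def fb_torque(t):
        if not feedback_on:
            return 0.0
        s = t - tm.delay
        y = history.state(s)
        s_ref = max(s, 0.0)
        phi_d, om_d, _ = desired_trajectory(s_ref, plan)
        return -tm.k_p * (y[0] - phi_d) - tm.k_d * (y[1] - om_d)

    def rhs(t, y):
        tau = float(recorded_torque(min(t, horizon))) + fb_torque(t)
        active = scheduler.active(t) if scheduler is not None else False
        alpha = equations_of_motion(ArmState(y[0], y[1]), tau, cfg.geometry,
                                    pert, active)
        return np.array([y[1], alpha])

    chunk = tm.delay if feedback_on else None
    _run_segments(rhs, y0, horizon,
                  [plan.movement_onset,
                   plan.movement_onset + plan.movement_duration],
                  chunk, scheduler, cfg, history,
                  impulse_duration=pert.impulse_duration)
    dt = cfg.solver.output_dt
    t = np.arange(0.0, horizon + dt / 2, dt)
    Y = history.sample(t)
    torque = np.array([float(recorded_torque(min(tk, horizon))) + fb_torque(tk)
                       for tk in t])
    return TorqueSimResult(
        t=t, phi=Y[0], omega=Y[1], torque=torque,
        impulse_onset=None if scheduler is None else scheduler.onset_time,
        impulse_offset=None if scheduler is None else scheduler.offset_time,
        meta=meta or {})
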