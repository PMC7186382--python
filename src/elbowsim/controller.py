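"""Hybrid intermittent open-loop + delayed spindle-feedback controller.

The open-loop command is a triphasic, piecewise-constant stimulation per
muscle: a co-contraction level holding the initial equilibrium posture,
an acceleration phase in which the agonists step to an optimized level
while the antagonists drop to a small floor, a braking phase, and a final
holding phase.  The stimulation levels of the holding and braking phases
are solved from static equilibrium (net elbow torque zero at the target
posture, with a chosen co-contraction level); the acceleration level and
its switching time are found by Bayesian optimization against the
minimum-jerk desired trajectory.

The closed-loop command is a time-delayed proportional-derivative signal
on the muscle-fiber length and contraction-velocity errors relative to the
values recorded during the unperturbed reference movement, normalized by
the optimal fiber length.  Open- and closed-loop commands are summed and
clipped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .config import FeedbackConfig, ModelConfig
from .mtu import isometric_equilibrium
from .routing import RoutingTables

logger = logging.getLogger(__name__)

__all__ = [
    "TriphasicPattern",
    "ReferenceTrajectory",
    "HistoryReference",
    "EquilibriumSolveSpec",
    "CalibrationError",
    "open_loop_u",
    "total_u",
    "closed_loop_u",
    "solve_equilibrium_stimulations",
    "record_reference",
    "optimize_acceleration_phase",
]


class CalibrationError(RuntimeError):
    """No stimulation set satisfies the requested equilibrium."""


@dataclass(frozen=True)
class TriphasicPattern:
    """Piecewise-constant open-loop stimulation parameters (one movement).

    Branch boundaries are right-continuous: at a switching instant the
    value of the later phase applies.
    """

    u0: np.ndarray            # per-muscle, holds the initial posture
    u_acc: float              # agonist level during the acceleration phase
    u_min: float              # antagonist floor during the acceleration phase
    u_dec: np.ndarray         # per-muscle, braking phase
    u_final: np.ndarray       # per-muscle, final holding phase
    t1: float                 # s, start of the braking phase
    t2: float                 # s, start of the final phase
    movement_onset: float     # s, start of the acceleration phase
    agonist_mask: np.ndarray  # boolean per muscle

    def __post_init__(self) -> None:
        if not self.movement_onset < self.t1 < self.t2:
            raise ValueError("need movement_onset < t1 < t2")
        for arr in (self.u0, self.u_dec, self.u_final):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("stimulations must lie in [0, 1]")
        if not 0 <= self.u_acc <= 1 or not 0 <= self.u_min <= 1:
            raise ValueError("stimulations must lie in [0, 1]")

    @property
    def breakpoints(self) -> tuple[float, float, float]:
        return (self.movement_onset, self.t1, self.t2)


def open_loop_u(t: float, pattern: TriphasicPattern) -> np.ndarray:
    """Per-muscle open-loop stimulation at time ``t``."""
    if t < pattern.movement_onset:
        return pattern.u0.copy()
    if t < pattern.t1:
        return np.where(pattern.agonist_mask, pattern.u_acc, pattern.u_min)
    if t < pattern.t2:
        return pattern.u_dec.copy()
    return pattern.u_final.copy()


def total_u(u_open, u_closed) -> np.ndarray:
    """Summed and clipped total stimulation (alpha motor-neuron drive)."""
    return np.clip(np.asarray(u_open) + np.asarray(u_closed), 0.0, 1.0)


@dataclass
class ReferenceTrajectory:
    """Recorded fiber lengths/velocities of the unperturbed movement.

    Dense uniform-time cubic splines of lambda (fiber length, m) and
    lambda-dot (fiber velocity, m/s) per muscle, covering [0, horizon];
    queries before time zero return the initial (equilibrium) values.
    """

    t_grid: np.ndarray
    lam_splines: list
    lam_dot_splines: list

    @classmethod
    def from_samples(cls, t: np.ndarray, l_ce: np.ndarray, v_ce: np.ndarray,
                     delay: float) -> "ReferenceTrajectory":
        if t[1] - t[0] > max(delay, 1e-9) and delay > 0:
            raise ValueError("reference grid is coarser than the feedback delay")
        return cls(
            t_grid=t,
            lam_splines=[CubicSpline(t, l_ce[:, i]) for i in range(l_ce.shape[1])],
            lam_dot_splines=[CubicSpline(t, v_ce[:, i]) for i in range(v_ce.shape[1])],
        )

    def _check(self, s: float) -> float:
        if s > self.t_grid[-1] + 1e-9:
            raise ValueError(
                f"reference trajectory ends at {self.t_grid[-1]:.3f} s, "
                f"queried at {s:.3f} s")
        return min(max(s, self.t_grid[0]), self.t_grid[-1])

    def lam(self, s: float) -> np.ndarray:
        s = self._check(s)
        return np.array([sp(s) for sp in self.lam_splines])

    def lam_dot(self, s: float) -> np.ndarray:
        s = self._check(s)
        return np.array([sp(s) for sp in self.lam_dot_splines])

    def values(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        return self.lam(s), self.lam_dot(s)


@dataclass
class HistoryReference:
    """Reference backed by the dense solver output of the recorded run.

    Evaluates the recording's own piecewise dense solution (and the same
    fiber-velocity recomputation), so replaying the closed loop on the
    identical unperturbed setup reproduces the reference exactly and the
    feedback signal vanishes to machine precision.
    """

    fiber_state_fn: object   # callable s -> (l_ce, v_ce)
    t_end: float

    def _check(self, s: float) -> float:
        if s > self.t_end + 1e-9:
            raise ValueError(
                f"reference trajectory ends at {self.t_end:.3f} s, "
                f"queried at {s:.3f} s")
        return min(s, self.t_end)

    def values(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        return self.fiber_state_fn(self._check(s))

    def lam(self, s: float) -> np.ndarray:
        return self.values(s)[0]

    def lam_dot(self, s: float) -> np.ndarray:
        return self.values(s)[1]


def closed_loop_u(t: float, state_at, ref: ReferenceTrajectory,
                  fb: FeedbackConfig, l_ce_opt: np.ndarray) -> np.ndarray:
    """Delayed PD feedback on fiber length/velocity errors (may be negative).

    ``state_at(s) -> (l_ce, v_ce)`` must provide the simulated fiber state
    at time ``s``; times before the simulation start return the initial
    equilibrium state, for which the error vanishes by construction.
    """
    if not fb.enabled or (fb.k_p == 0.0 and fb.k_d == 0.0):
        return np.zeros_like(l_ce_opt)
    s = t - fb.delay
    l_ce, v_ce = state_at(s)
    lam, lam_dot = ref.values(s)
    err_l = l_ce - lam
    err_v = v_ce - lam_dot
    return fb.k_p / l_ce_opt * err_l + fb.k_d / l_ce_opt * err_v


def record_reference(result, delay: float):
    """Build the (lambda, lambda-dot) reference from an unperturbed run.

    Uses the run's dense solver output when available (exact replay), and
    falls back to cubic splines of the sampled time series (e.g. for runs
    reloaded from disk).
    """
    if np.max(np.abs(result.u_closed)) > 0:
        raise ValueError("reference must be recorded from an open-loop run")
    fn = getattr(result, "fiber_state_fn", None)
    if fn is not None:
        return HistoryReference(fiber_state_fn=fn, t_end=float(result.t[-1]))
    return ReferenceTrajectory.from_samples(result.t, result.l_ce,
                                            result.v_ce, delay)


# --------------------------------------------------------------------------
# equilibrium-point solving
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumSolveSpec:
    target_angle: float          # rad
    u_des: float                 # desired co-contraction level
    bias_torque: float = 0.0     # N m, constant external torque to balance
    torque_tolerance: float = 1e-3   # N m

    def __post_init__(self) -> None:
        if self.torque_tolerance <= 0:
            raise ValueError("torque_tolerance must be > 0")


def _static_torque(u: np.ndarray, lengths: np.ndarray, arms: np.ndarray,
                   cfg: ModelConfig) -> float:
    tau = 0.0
    for i, m in enumerate(cfg.muscles):
        _, _, force = isometric_equilibrium(float(u[i]), float(lengths[i]),
                                            m.params)
        tau += arms[i] * force
    return tau


def solve_equilibrium_stimulations(spec: EquilibriumSolveSpec,
                                   cfg: ModelConfig,
                                   tables: RoutingTables,
                                   objective: str = "squared") -> np.ndarray:
    """Stimulations holding the target posture in static equilibrium.

    Minimizes the deviation of the stimulations from the desired
    co-contraction level subject to zero net joint torque (muscle torque
    balancing any constant bias torque) at the steady state of the
    activation and contraction dynamics.  ``objective`` selects the
    squared deviation (default; makes the co-contraction level an
    attractor) or the plain linear sum.
    """
    phi = spec.target_angle
    lengths = tables.lengths(phi)
    arms = tables.moment_arms(phi)
    n = len(cfg.muscles)

    def torque_balance(u):
        return _static_torque(u, lengths, arms, cfg) + spec.bias_torque

    if objective == "squared":
        def obj(u):
            return float(np.sum((u - spec.u_des) ** 2))
    elif objective == "linear":
        def obj(u):
            return float(np.sum(u - spec.u_des))
    else:
        raise ValueError(f"unknown objective {objective!r}")

    best = None
    for x0_scale in (1.0, 0.5, 2.0, 4.0):
        x0 = np.full(n, min(max(spec.u_des * x0_scale, 1e-3), 0.9))
        res = minimize(
            obj, x0, method="SLSQP", bounds=[(0.0, 1.0)] * n,
            constraints=[{"type": "eq", "fun": torque_balance}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if abs(torque_balance(res.x)) < spec.torque_tolerance:
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        direction = "flexion" if spec.bias_torque < 0 else "extension"
        raise CalibrationError(
            f"no stimulation set balances the joint at "
            f"{np.degrees(phi):.1f} deg (insufficient {direction} torque)")
    return np.clip(best.x, 0.0, 1.0)


# --------------------------------------------------------------------------
# acceleration-phase optimization
# --------------------------------------------------------------------------

def optimize_acceleration_phase(objective, cfg: ModelConfig,
                                seed: int) -> tuple[float, float, float]:
    """Optimize (u_acc, t1) of the acceleration phase.

    ``objective(u_acc, t1)`` must return the squared pointwise deviation
    of the simulated from the desired trajectory (any non-finite value is
    treated as a rejected candidate).  Returns ``(u_acc, t1, best_value)``;
    deterministic for a fixed seed.

    The ``u_acc`` coordinate is searched in log space (stimulation levels
    act multiplicatively on muscle force) and the Bayesian stage is
    followed by a short compass-search polish, because the tracking
    objective has a valley that is narrow in ``u_acc`` relative to its
    search range.
    """
    from .optim import bayes_minimize, pattern_search

    opt = cfg.optimization
    log_bounds = (np.log(opt.u_acc_bounds[0]), np.log(opt.u_acc_bounds[1]))
    bounds = [log_bounds, opt.t1_bounds]
    # rejected candidates (anatomical-range violations) get a finite
    # penalty on the scale of the worst possible squared deviation, so
    # the surrogate model stays well conditioned
    penalty = 10.0

    def f(x):
        u_acc = float(np.exp(x[0]))
        val = objective(u_acc, float(x[1]))
        if not np.isfinite(val):
            logger.warning("candidate u_acc=%.3f t1=%.3f rejected "
                           "(non-finite objective)", u_acc, x[1])
            return penalty
        return min(float(val), penalty)

    x_best, f_best, _ = bayes_minimize(
        f, bounds, n_init=opt.bayes_n_init, n_total=opt.bayes_budget,
        seed=seed)
    step = np.array([(b[1] - b[0]) / 100 for b in bounds])
    x_best, f_best, _ = pattern_search(
        f, x_best, step, bounds,
        budget=max(16, opt.bayes_budget // 2))
    return float(np.exp(x_best[0])), float(x_best[1]), float(f_best)
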