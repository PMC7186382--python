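"""Single degree-of-freedom rigid-body dynamics of the forearm.

The shoulder is locked at a fixed angle, so the only generalized
coordinate is the elbow flexion angle.  The forearm (including the hand
and the inertia contribution of the exoskeleton robot used in the
perturbation experiments this package emulates) rotates about the elbow
under the active muscle torque, intrinsic joint damping, and the
experimental perturbation loads:

* static perturbations: an additive change of the moment of inertia or of
  the joint damping, present for the whole trial (the robot renders them
  continuously), plus an optional constant bias torque mimicking gravity;
* dynamic perturbations: a rectangular torque impulse that fires once a
  configured fraction of the movement amplitude has been traversed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger(__name__)

__all__ = [
    "ArmGeometry",
    "ArmState",
    "PerturbationKind",
    "PerturbationSpec",
    "RangeError",
    "equations_of_motion",
    "ImpulseScheduler",
]


class RangeError(RuntimeError):
    """Elbow angle left the configured anatomical range during integration."""


@dataclass(frozen=True)
class ArmGeometry:
    """Segment geometry and forearm inertial properties (SI units).

    ``forearm_inertia_about_elbow`` already includes the exoskeleton
    contribution; ``shoulder_lock_angle`` is fixed for a run and only
    documents the experimental posture (movements are in the horizontal
    plane unless a bias torque is applied, so it does not enter the
    dynamics).  Angles of the anatomical range are in radians,
    flexion-positive, zero at full extension.
    """

    upper_arm_length: float = 0.30
    forearm_length: float = 0.45
    forearm_mass: float = 1.8
    forearm_com_distance: float = 0.18
    forearm_inertia_about_elbow: float = 0.15
    shoulder_lock_angle_deg: float = 30.0
    intrinsic_joint_damping: float = 0.0
    phi_min: float = math.radians(5.0)
    phi_max: float = math.radians(150.0)

    def __post_init__(self) -> None:
        for name in ("upper_arm_length", "forearm_length", "forearm_mass",
                     "forearm_com_distance", "forearm_inertia_about_elbow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.phi_min >= self.phi_max:
            raise ValueError("phi_min must be below phi_max")


@dataclass
class ArmState:
    elbow_angle: float       # rad, flexion positive
    elbow_velocity: float    # rad/s


class PerturbationKind(str, Enum):
    NONE = "none"
    INERTIA_DELTA = "inertia_delta"
    DAMPING_DELTA = "damping_delta"
    TORQUE_IMPULSE = "torque_impulse"


@dataclass(frozen=True)
class PerturbationSpec:
    """One experimental perturbation; only the fields of ``kind`` are read."""

    kind: PerturbationKind = PerturbationKind.NONE
    inertia_delta: float = 0.0           # kg m^2
    damping_delta: float = 0.0           # N m s / rad
    constant_torque: float = 0.0         # N m (gravity-mimicking bias)
    impulse_magnitude: float = 0.0       # N m
    impulse_onset_fraction: float = 0.25
    impulse_duration: float = 0.0375     # s

    def __post_init__(self) -> None:
        if self.kind == PerturbationKind.TORQUE_IMPULSE and self.impulse_duration <= 0:
            raise ValueError("impulse_duration must be > 0 for torque impulses")

    @property
    def effective_inertia_delta(self) -> float:
        return self.inertia_delta if self.kind == PerturbationKind.INERTIA_DELTA else 0.0

    @property
    def effective_damping_delta(self) -> float:
        return self.damping_delta if self.kind == PerturbationKind.DAMPING_DELTA else 0.0

    @property
    def effective_impulse(self) -> float:
        return self.impulse_magnitude if self.kind == PerturbationKind.TORQUE_IMPULSE else 0.0


NO_PERTURBATION = PerturbationSpec()


def equations_of_motion(state: ArmState, active_joint_torque: float,
                        geom: ArmGeometry,
                        pert: PerturbationSpec = NO_PERTURBATION,
                        pert_active: bool = False) -> float:
    """Elbow angular acceleration (rad/s^2).

    ``pert_active`` gates only the torque impulse; inertia/damping deltas
    and the constant bias torque act for the whole trial.
    """
    inertia = geom.forearm_inertia_about_elbow + pert.effective_inertia_delta
    if inertia <= 0:
        raise ValueError(f"non-positive effective inertia {inertia:.4g} kg m^2")
    damping = geom.intrinsic_joint_damping + pert.effective_damping_delta
    torque = (active_joint_torque
              - damping * state.elbow_velocity
              + pert.constant_torque
              + (pert.effective_impulse if pert_active else 0.0))
    return torque / inertia


class ImpulseScheduler:
    """Latching activation window of the torque-impulse perturbation.

    The impulse fires the first time the traversed angle reaches the
    configured fraction of the movement amplitude and stays active for the
    impulse duration; it never re-fires.
    """

    def __init__(self, pert: PerturbationSpec, start_angle: float,
                 end_angle: float):
        if pert.kind != PerturbationKind.TORQUE_IMPULSE:
            raise ValueError("ImpulseScheduler requires kind=torque_impulse")
        self.pert = pert
        self.start_angle = start_angle
        self.threshold = pert.impulse_onset_fraction * abs(end_angle - start_angle)
        self.onset_time: float | None = None

    def onset_event(self, t: float, phi: float) -> float:
        """Sign-changing event function for integrator event location."""
        return abs(phi - self.start_angle) - self.threshold

    def latch(self, t: float) -> None:
        if self.onset_time is None:
            self.onset_time = t

    @property
    def offset_time(self) -> float | None:
        if self.onset_time is None:
            return None
        return self.onset_time + self.pert.impulse_duration

    def active(self, t: float) -> bool:
        return (self.onset_time is not None
                and self.onset_time <= t < self.offset_time)

    def warn_if_never_fired(self) -> None:
        if self.onset_time is None:
            logger.warning(
                "torque impulse never fired: movement never traversed "
                "%.3g rad", self.threshold,
            )
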