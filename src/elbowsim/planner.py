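"""Minimum-jerk planning of the desired elbow-angle trajectory.

Point-to-point reaching movements of the human arm show stereotyped,
bell-shaped velocity profiles.  The classical account models the desired
joint trajectory as the fifth-order polynomial that minimises integrated
squared jerk between a start and an end posture, with zero velocity and
acceleration at both ends.  The controller treats this trajectory as the
output of a higher-level planning stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MovementPlan", "desired_trajectory"]


@dataclass(frozen=True)
class MovementPlan:
    """Start/end elbow angles (rad) and timing of a point-to-point movement."""

    start_angle: float
    end_angle: float
    movement_onset: float = 0.1
    movement_duration: float = 0.6

    def __post_init__(self) -> None:
        if self.movement_duration <= 0:
            raise ValueError("movement_duration must be positive")
        if self.movement_onset < 0:
            raise ValueError("movement_onset must be non-negative")

    @property
    def amplitude(self) -> float:
        return self.end_angle - self.start_angle


def desired_trajectory(t, plan: MovementPlan):
    """Minimum-jerk angle, velocity and acceleration at time(s) ``t``.

    Before the movement onset the trajectory is clamped to the start
    posture, after onset + duration to the end posture (zero velocity and
    acceleration in both cases).  Accepts scalars or arrays.

    Returns
    -------
    (angle, velocity, acceleration) in rad, rad/s, rad/s^2.
    """
    t = np.asarray(t, dtype=float)
    s = np.clip((t - plan.movement_onset) / plan.movement_duration, 0.0, 1.0)
    amp = plan.amplitude
    T = plan.movement_duration
    # x(s) = 10 s^3 - 15 s^4 + 6 s^5, the unique quintic with rest-to-rest
    # boundary conditions.
    angle = plan.start_angle + amp * (10 * s**3 - 15 * s**4 + 6 * s**5)
    velocity = amp / T * (30 * s**2 - 60 * s**3 + 30 * s**4)
    acceleration = amp / T**2 * (60 * s - 180 * s**2 + 120 * s**3)
    if angle.ndim == 0:
        return float(angle), float(velocity), float(acceleration)
    return angle, velocity, acceleration
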