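import math

import numpy as np
import pytest

from elbowsim.experiments import (STATIC_TYPES, MetricError, cost_eq5,
                                  dysmetria, early_velocity,
                                  feedback_contribution,
                                  first_correction_time, kinematic_onset,
                                  velocity_quotient)
from tests.conftest import make_sim_result


def test_early_velocity_on_constructed_ramp():
    """omega = 100 t deg/s: onset at 0.1 s, evaluated at 0.255 s -> 25.5."""
    t = np.linspace(0.0, 1.2, 1201)
    omega = np.radians(100.0) * t
    assert kinematic_onset(t, omega) == pytest.approx(0.1, abs=1e-9)
    assert early_velocity(t, omega) == pytest.approx(25.5, abs=1e-6)


def test_early_velocity_sign_follows_movement_direction():
    t = np.linspace(0.0, 1.2, 1201)
    omega = -np.radians(100.0) * t
    assert early_velocity(t, omega) == pytest.approx(-25.5, abs=1e-6)


def test_early_velocity_errors():
    t = np.linspace(0.0, 1.2, 1201)
    with pytest.raises(MetricError):
        early_velocity(t, np.full_like(t, np.radians(1.0)))   # never moves
    t_short = np.linspace(0.0, 0.2, 201)
    with pytest.raises(MetricError):
        early_velocity(t_short, np.radians(100.0) * t_short)  # ends too soon


def _overshoot_trajectory():
    """Rise smoothly to 32 deg by 0.5 s, hold, settle to 30 deg by 1 s."""
    t = np.linspace(0.0, 1.1, 2201)
    phi = np.empty_like(t)
    omega = np.empty_like(t)
    rise = (t >= 0.1) & (t <= 0.5)
    s = math.pi * (t[rise] - 0.1) / 0.4
    phi[t < 0.1] = 0.0
    omega[t < 0.1] = 0.0
    phi[rise] = np.radians(16.0) * (1 - np.cos(s))
    omega[rise] = np.radians(16.0) * math.pi / 0.4 * np.sin(s)
    hold = (t > 0.5) & (t < 0.7)
    phi[hold] = np.radians(32.0)
    omega[hold] = 0.0
    fall = t >= 0.7
    phi[fall] = np.radians(32.0) - np.radians(2.0) * np.clip(
        (t[fall] - 0.7) / 0.3, 0, 1)
    omega[fall] = np.where(t[fall] <= 1.0, -np.radians(2.0) / 0.3, 0.0)
    return t, phi, omega


def test_dysmetria_on_constructed_overshoot():
    """32 deg at first correction, 30 deg at trial end -> -2 deg."""
    t, phi, omega = _overshoot_trajectory()
    t_fc = first_correction_time(t, omega)
    assert 0.49 < t_fc < 0.55
    assert dysmetria(t, phi, omega) == pytest.approx(-2.0, abs=0.02)


def test_dysmetria_zero_for_clean_stop():
    t, phi, omega = _overshoot_trajectory()
    # cut the settling: hold the overshoot position to the end
    phi = np.where(t > 0.5, np.radians(32.0), phi)
    omega = np.where(t > 0.5, 0.0, omega)
    assert dysmetria(t, phi, omega) == pytest.approx(0.0, abs=0.02)


def test_dysmetria_requires_full_trial():
    t = np.linspace(0, 0.8, 801)
    with pytest.raises(MetricError):
        dysmetria(t, np.zeros_like(t), np.zeros_like(t))


def test_first_correction_falls_back_to_trial_end():
    t = np.linspace(0, 1.1, 1101)
    omega = np.radians(50.0) * np.ones_like(t)   # never slows down
    omega[0] = 0.0
    assert first_correction_time(t, omega) == pytest.approx(1.0)


def test_velocity_quotient_arithmetic():
    t = np.linspace(0, 1, 16001)   # grid resolves the 0.3375 s kink
    omega = np.interp(t, [0.0, 0.3, 0.3375, 1.0], [1.0, 1.0, 2.0, 2.0])
    assert velocity_quotient(t, omega, 0.3, 0.0375) == pytest.approx(
        0.5, abs=1e-3)
    assert velocity_quotient(t, omega, 0.3, 0.100) == pytest.approx(0.5)
    with pytest.raises(MetricError):
        velocity_quotient(t, np.zeros_like(t), 0.3, 0.0375)


def test_cost_eq5_zero_at_reference_means(default_cfg):
    ref = default_cfg.reference
    deltas = {k: (ref.early_velocity_mean[k], ref.dysmetria_mean[k])
              for k in STATIC_TYPES}
    assert cost_eq5(deltas, ref) == pytest.approx(0.0, abs=1e-12)


def test_cost_eq5_unit_deviations(default_cfg):
    """Each term shifted by the max cross-type SD contributes exactly 1."""
    ref = default_cfg.reference
    sd_v = max(ref.early_velocity_sd[k] for k in STATIC_TYPES)
    sd_d = max(ref.dysmetria_sd[k] for k in STATIC_TYPES)
    deltas = {k: (ref.early_velocity_mean[k] + sd_v,
                  ref.dysmetria_mean[k] + sd_d) for k in STATIC_TYPES}
    assert cost_eq5(deltas, ref) == pytest.approx(8.0, rel=1e-12)
    with pytest.raises(ValueError):
        cost_eq5({"inertia_up": (0, 0)}, ref)


def test_feedback_contribution_arithmetic():
    t = np.linspace(0, 0.1, 11)
    n = len(t)
    # constant signals u_open = 0.5, u_closed = 0.1 -> 0.1 / 0.6 = 1/6
    res = make_sim_result(t, np.zeros(n), np.zeros(n),
                          np.full((n, 2), 0.5), np.full((n, 2), 0.1))
    assert feedback_contribution(res) == pytest.approx(1.0 / 6.0)


def test_feedback_contribution_clipped_convention():
    t = np.linspace(0, 0.1, 11)
    n = len(t)
    # u_open = 1.0, u_closed = 0.2 -> total clips to 1.0 -> 0.2
    res = make_sim_result(t, np.zeros(n), np.zeros(n),
                          np.ones((n, 2)), np.full((n, 2), 0.2))
    assert feedback_contribution(res) == pytest.approx(0.2)


def test_feedback_contribution_open_loop_is_zero():
    t = np.linspace(0, 0.1, 11)
    n = len(t)
    res = make_sim_result(t, np.zeros(n), np.zeros(n),
                          np.full((n, 2), 0.5), np.zeros((n, 2)))
    assert feedback_contribution(res) == 0.0


def test_feedback_contribution_eps_guards_suppressed_drive():
    t = np.linspace(0, 0.1, 11)
    n = len(t)
    # feedback cancels the whole drive: total clips to 0, ratio = 0.3/eps
    res = make_sim_result(t, np.zeros(n), np.zeros(n),
                          np.full((n, 2), 0.2), np.full((n, 2), -0.3))
    assert feedback_contribution(res, eps=1e-3) == pytest.approx(300.0)
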