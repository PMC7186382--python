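import math

import numpy as np
import pytest
from scipy.optimize import minimize

from elbowsim.routing import (DeflectionEllipse, GeometryError, PathSpec,
                              RoutingTables, joint_loads, moment_arm,
                              solve_path)

L = 0.30  # upper-arm length used throughout


def _circle_wrap_closed_form(p0, p1, c, r):
    """Shortest p0 -> circle -> p1 length: two tangents plus the arc."""
    p0, p1, c = map(np.asarray, (p0, p1, c))
    d0, d1 = np.linalg.norm(p0 - c), np.linalg.norm(p1 - c)
    assert d0 > r and d1 > r
    tan0 = math.sqrt(d0 * d0 - r * r)
    tan1 = math.sqrt(d1 * d1 - r * r)
    gamma = math.acos(np.clip(np.dot(p0 - c, p1 - c) / (d0 * d1), -1, 1))
    wrap = gamma - math.acos(r / d0) - math.acos(r / d1)
    assert wrap > 0, "test geometry must actually wrap"
    return tan0 + tan1 + r * wrap, wrap


def _folded_insertion_world(x_f, y_f):
    """World position of a forearm-frame point at phi = pi (folded arm)."""
    return np.array([L - x_f, -y_f])


# circle obstacle slightly off the chord between origin and insertion
WRAP_CIRCLE = DeflectionEllipse(center=(0.105, 0.0), semi_axes=(0.03, 0.03),
                                owning_segment="upper_arm")
WRAP_SPEC = PathSpec(name="wrap", origin_point=(0.10, 0.05),
                     insertion_point=(0.20, 0.05),
                     deflection_ellipses=(WRAP_CIRCLE,))
PHI_FOLDED = math.pi


def test_straight_path_without_obstacle():
    spec = PathSpec(name="straight", origin_point=(0.10, 0.05),
                    insertion_point=(0.20, 0.05))
    res = solve_path(PHI_FOLDED, spec, L)
    p1 = _folded_insertion_world(0.20, 0.05)
    expected = np.linalg.norm(np.array([0.10, 0.05]) - p1)
    assert res.mtu_length == pytest.approx(expected, abs=1e-12)
    assert not res.path_deflected


def test_untouched_obstacle_leaves_path_straight():
    far = DeflectionEllipse(center=(0.25, 0.10), semi_axes=(0.01, 0.01))
    spec = PathSpec(name="clear", origin_point=(0.10, 0.05),
                    insertion_point=(0.20, 0.05),
                    deflection_ellipses=(far,))
    res = solve_path(PHI_FOLDED, spec, L)
    p1 = _folded_insertion_world(0.20, 0.05)
    expected = np.linalg.norm(np.array([0.10, 0.05]) - p1)
    assert res.mtu_length == pytest.approx(expected, abs=1e-12)
    assert not res.wrapped[0]
    assert np.allclose(res.contact_force_unit[0], 0.0)


def test_circular_wrap_matches_closed_form():
    res = solve_path(PHI_FOLDED, WRAP_SPEC, L)
    p0 = np.array([0.10, 0.05])
    p1 = _folded_insertion_world(0.20, 0.05)
    expected, _ = _circle_wrap_closed_form(p0, p1, (0.105, 0.0), 0.03)
    assert res.path_deflected
    assert res.mtu_length == pytest.approx(expected, abs=1e-9)


def test_wrap_is_the_shortest_tangent_path():
    """Independent oracle: optimize the two boundary angles directly."""
    res = solve_path(PHI_FOLDED, WRAP_SPEC, L)
    p0 = np.array([0.10, 0.05])
    p1 = _folded_insertion_world(0.20, 0.05)
    c = np.array([0.105, 0.0])
    r = 0.03

    def _penetration(p, q):
        """Max depth by which segment p-q enters the circle (sampled)."""
        s = np.linspace(0, 1, 64)[:, None]
        pts = p + s * (q - p)
        return max(0.0, r - np.min(np.linalg.norm(pts - c, axis=1)))

    def length(x):
        th_a, th_b = x
        a = c + r * np.array([math.cos(th_a), math.sin(th_a)])
        b = c + r * np.array([math.cos(th_b), math.sin(th_b)])
        arc = r * abs(th_b - th_a)
        penalty = 100.0 * (_penetration(p0, a) + _penetration(b, p1))
        return (np.linalg.norm(p0 - a) + arc + np.linalg.norm(b - p1)
                + penalty)

    best = math.inf
    for th0 in np.linspace(-math.pi, math.pi, 8, endpoint=False):
        out = minimize(length, [th0, th0 + 0.3], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 4000})
        best = min(best, out.fun)
    assert res.mtu_length == pytest.approx(best, abs=1e-6)


def test_contact_force_unit_of_circular_wrap():
    res = solve_path(PHI_FOLDED, WRAP_SPEC, L)
    p0 = np.array([0.10, 0.05])
    p1 = _folded_insertion_world(0.20, 0.05)
    _, wrap = _circle_wrap_closed_form(p0, p1, (0.105, 0.0), 0.03)
    f = np.asarray(res.contact_force_unit[0])
    # frictionless wrap: |F| per unit tension = 2 sin(wrap angle / 2)
    assert np.linalg.norm(f) == pytest.approx(2 * math.sin(wrap / 2),
                                              abs=1e-8)
    # the resultant acts along the bisector, pushing into the obstacle
    t_in, t_out = res.tangent_points[0]
    mid = 0.5 * (np.asarray(t_in) + np.asarray(t_out))
    into = np.array([0.105, 0.0]) - mid
    cosang = np.dot(f, into) / (np.linalg.norm(f) * np.linalg.norm(into))
    assert cosang == pytest.approx(1.0, abs=1e-6)


def test_moment_arm_matches_finite_difference(ctx):
    h = 1e-6
    geom = ctx.cfg.geometry
    for m in ctx.cfg.muscles:
        for phi in np.radians([40.0, 75.0, 110.0]):
            ma = moment_arm(phi, m.path, geom.upper_arm_length)
            l_hi = solve_path(phi + h, m.path, geom.upper_arm_length).mtu_length
            l_lo = solve_path(phi - h, m.path, geom.upper_arm_length).mtu_length
            assert ma == pytest.approx(-(l_hi - l_lo) / (2 * h), abs=1e-6)


def test_moment_arm_signs(ctx):
    phi = math.radians(75.0)
    geom = ctx.cfg.geometry
    for m in ctx.cfg.muscles:
        ma = moment_arm(phi, m.path, geom.upper_arm_length)
        assert (ma > 0) == m.flexor


def test_routing_tables_match_direct_solution(ctx):
    geom = ctx.cfg.geometry
    for phi in np.radians([35.0, 62.5, 88.0, 120.0]):
        lengths = ctx.tables.lengths(phi)
        arms = ctx.tables.moment_arms(phi)
        for i, m in enumerate(ctx.cfg.muscles):
            res = solve_path(phi, m.path, geom.upper_arm_length)
            assert lengths[i] == pytest.approx(res.mtu_length, abs=1e-6)
            assert arms[i] == pytest.approx(res.moment_arm, abs=1e-5)


def test_virtual_work_balance(ctx):
    """Joint power equals sum of F * (-dl/dt) along an imposed motion."""
    geom = ctx.cfg.geometry
    t = np.linspace(0, 1, 2001)
    phi = np.radians(60 + 30 * np.sin(2 * math.pi * t))
    omega = np.gradient(phi, t)
    forces = np.array([30.0, 20.0, 10.0, 5.0][:ctx.n_muscles])
    lengths = np.stack([ctx.tables.lengths(p) for p in phi])
    dl_dt = np.gradient(lengths, t, axis=0)
    torque = np.array([
        float(np.dot(forces, ctx.tables.moment_arms(p))) for p in phi])
    power_joint = torque * omega
    power_muscle = -(dl_dt * forces).sum(axis=1)
    mask = slice(10, -10)   # drop the end-effect samples of np.gradient
    assert np.allclose(power_joint[mask], power_muscle[mask],
                       atol=1e-3 * np.max(np.abs(power_joint)))


def test_joint_loads_newton_balance(ctx):
    geom = ctx.cfg.geometry
    phi = math.radians(80.0)
    specs = [m.path for m in ctx.cfg.muscles]
    forces = np.array([50.0, 40.0, 25.0, 10.0][:ctx.n_muscles])
    a_com = np.array([0.3, -0.2])
    torque, constraint, contacts = joint_loads(
        phi, forces, specs, geom.upper_arm_length,
        com_acceleration=a_com, forearm_mass=geom.forearm_mass)
    muscle_on_forearm = np.zeros(2)
    for f_i, spec in zip(forces, specs):
        res = solve_path(phi, spec, geom.upper_arm_length)
        muscle_on_forearm += f_i * res.forearm_force_unit
    assert np.allclose(constraint + muscle_on_forearm,
                       geom.forearm_mass * a_com, atol=1e-9)
    expected_torque = float(np.dot(
        forces, [solve_path(phi, s, geom.upper_arm_length).moment_arm
                 for s in specs]))
    assert torque == pytest.approx(expected_torque, abs=1e-9)
    with pytest.raises(ValueError):
        joint_loads(phi, -forces, specs, geom.upper_arm_length)


def test_invalid_geometry_rejected():
    with pytest.raises(GeometryError):
        DeflectionEllipse(center=(0, 0), semi_axes=(0.0, 0.01))
    with pytest.raises(GeometryError):
        DeflectionEllipse(center=(0, 0), semi_axes=(0.01, 0.01),
                          owning_segment="hand")
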