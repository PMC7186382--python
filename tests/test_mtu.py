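import math

import numpy as np
import pytest

from elbowsim.mtu import (MTUParams, MTUState, activation_fixed_point,
                          activation_rate, fiber_velocity, force_length,
                          force_velocity_factor, isometric_equilibrium,
                          mtu_force, pee_force, see_force)

P = MTUParams(name="test", f_max=1000.0, l_ce_opt=0.10, see_rest_length=0.20)


def test_force_length_peaks_at_optimum():
    assert force_length(1.0, P) == 1.0
    assert force_length(0.7, P) < 1.0
    assert force_length(1.3, P) < 1.0
    # symmetric bell
    assert force_length(0.8, P) == pytest.approx(force_length(1.2, P))


def test_force_velocity_branches():
    f_iso = 0.8
    assert force_velocity_factor(0.0, f_iso, P) == pytest.approx(f_iso)
    # concentric: force drops with shortening speed, zero at v_max
    assert force_velocity_factor(-1.0, f_iso, P) < f_iso
    v_zero = -f_iso * P.hill_b_rel / P.hill_a_rel
    assert force_velocity_factor(v_zero, f_iso, P) == pytest.approx(0.0, abs=1e-12)
    # eccentric: force exceeds isometric, bounded by the asymptote
    f_ecc = force_velocity_factor(0.5, f_iso, P)
    assert f_iso < f_ecc < P.eccentric_force_factor * f_iso
    assert force_velocity_factor(50.0, f_iso, P) == pytest.approx(
        P.eccentric_force_factor * f_iso, rel=1e-2)


def test_force_velocity_slope_continuity():
    # eccentric slope at v=0 equals eccentric_slope_factor times concentric
    f_iso = 0.6
    h = 1e-7
    slope_con = (force_velocity_factor(0.0, f_iso, P)
                 - force_velocity_factor(-h, f_iso, P)) / h
    slope_ecc = (force_velocity_factor(h, f_iso, P)
                 - force_velocity_factor(0.0, f_iso, P)) / h
    assert slope_ecc == pytest.approx(P.eccentric_slope_factor * slope_con,
                                      rel=1e-4)


def test_see_force_piecewise():
    assert see_force(P.see_rest_length, P) == 0.0
    assert see_force(0.9 * P.see_rest_length, P) == 0.0
    # quadratic toe, then linear; continuous value and slope at the knee
    et = P.see_toe_strain
    k = P.see_linear_stiffness * P.f_max
    l_knee = P.see_rest_length * (1 + et)
    assert see_force(l_knee, P) == pytest.approx(0.5 * k * et)
    h = 1e-9 * P.see_rest_length
    slope_lo = (see_force(l_knee, P) - see_force(l_knee - h, P)) / h
    slope_hi = (see_force(l_knee + h, P) - see_force(l_knee, P)) / h
    assert slope_lo == pytest.approx(slope_hi, rel=1e-4)


def test_pee_force():
    assert pee_force(P.l_ce_opt * P.pee_slack_norm, P) == 0.0
    assert pee_force(0.8 * P.l_ce_opt, P) == 0.0
    l = 1.2 * P.l_ce_opt
    assert pee_force(l, P) == pytest.approx(
        P.pee_stiffness * P.f_max * (1.2 - P.pee_slack_norm) ** 2)


def test_activation_fixed_point_bounds_and_monotonicity():
    for l_n in (0.7, 1.0, 1.3):
        a0 = activation_fixed_point(0.0, l_n, P)
        a1 = activation_fixed_point(1.0, l_n, P)
        assert a0 == pytest.approx(P.activation_min)
        assert P.activation_min <= a1 <= 1.0
        us = np.linspace(0, 1, 11)
        a = [activation_fixed_point(u, l_n, P) for u in us]
        assert np.all(np.diff(a) > 0)
    # longer fibers activate more strongly at the same stimulation
    assert (activation_fixed_point(0.2, 1.2, P)
            > activation_fixed_point(0.2, 0.8, P))


def test_activation_rate_vanishes_at_fixed_point():
    u, l_ce = 0.3, 0.11
    a_inf = activation_fixed_point(u, l_ce / P.l_ce_opt, P)
    assert activation_rate(a_inf, u, l_ce, P) == pytest.approx(0.0, abs=1e-14)
    # first-order relaxation with the configured rate constant
    assert activation_rate(a_inf - 0.1, u, l_ce, P) == pytest.approx(
        0.1 * P.activation_rate_const)


def _residual(v_ce, l_ce, act, l_mtu, v_mtu):
    l_n = l_ce / P.l_ce_opt
    f_iso = act * force_length(l_n, P)
    f_ce = P.f_max * force_velocity_factor(v_ce / P.l_ce_opt, f_iso, P)
    return (f_ce + pee_force(l_ce, P)
            - see_force(l_mtu - l_ce, P)
            - P.serial_damping * (v_mtu - v_ce))


@pytest.mark.parametrize("act,l_mtu,v_mtu", [
    (0.05, 0.302, 0.0),    # slack-ish, low drive
    (0.80, 0.305, 0.0),    # strong drive, stretched tendon -> shortening
    (0.30, 0.306, 0.10),   # lengthening MTU
    (0.90, 0.300, -0.20),  # shortening MTU
])
def test_fiber_velocity_satisfies_force_balance(act, l_mtu, v_mtu):
    l_ce = 0.10
    v = fiber_velocity(l_ce, act, l_mtu, v_mtu, P)
    assert abs(_residual(v, l_ce, act, l_mtu, v_mtu)) < 1e-6 * P.f_max


def test_mtu_force_consistency():
    state = MTUState(l_ce=0.10, activity=0.5)
    force, v_ce = mtu_force(0.305, 0.0, state, P)
    assert force == pytest.approx(
        see_force(0.305 - state.l_ce, P) - P.serial_damping * v_ce)
    assert force >= 0.0


def test_isometric_equilibrium():
    l_mtu = 0.305
    l_ce, act, force = isometric_equilibrium(0.4, l_mtu, P)
    assert act == pytest.approx(
        activation_fixed_point(0.4, l_ce / P.l_ce_opt, P))
    assert force == pytest.approx(see_force(l_mtu - l_ce, P))
    # internal balance holds at zero fiber velocity
    assert abs(_residual(0.0, l_ce, act, l_mtu, 0.0)) < 1e-7 * P.f_max
    # monotone: stronger drive shortens the fiber and raises the force
    l2, _, f2 = isometric_equilibrium(0.8, l_mtu, P)
    assert l2 < l_ce and f2 > force


def test_parameter_validation():
    with pytest.raises(ValueError):
        MTUParams(name="bad", f_max=-1.0, l_ce_opt=0.1)
    with pytest.raises(ValueError):
        MTUParams(name="bad", f_max=1.0, l_ce_opt=0.1, activation_min=0.0)
    with pytest.raises(ValueError):
        MTUParams(name="bad", f_max=1.0, l_ce_opt=0.1,
                  eccentric_force_factor=1.0)
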