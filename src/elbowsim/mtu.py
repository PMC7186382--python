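"""Hill-type muscle-tendon unit with length-dependent activation dynamics.

Each muscle-tendon unit (MTU) is a four-element Hill-type model:

* CE  - contractile element with a Gaussian isometric force-length curve
        peaking at ``l_ce_opt`` and a hyperbolic force-velocity relation
        (classical Hill hyperbola for shortening, a saturating eccentric
        branch for lengthening),
* PEE - parallel elastic element, quadratic above a slack length,
* SEE - serial elastic element (tendon + aponeurosis), quadratic toe
        region followed by a linear region,
* SDE - serial damping element, linear in tendon lengthening velocity.

The neural drive enters through activation dynamics in the style of Hatze:
a first-order relaxation of the muscle activity ``a`` toward a fixed point
that grows sigmoidally with the stimulation ``u`` and depends on the
normalized fiber length (longer fibers sensitise the calcium-troponin
binding, so the same stimulation yields a higher steady-state activity).

The fiber velocity is not an independent state: at every instant it is the
unique value for which the force of CE + PEE balances the force of
SEE + SDE.  Because the CE force is non-decreasing in fiber velocity and
the damping term is strictly increasing, the balance has a unique root,
which is solved in closed form per force-velocity branch (quadratic in the
normalized velocity) with a bracketed numerical fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "MTUParams",
    "MTUState",
    "activation_fixed_point",
    "activation_rate",
    "fiber_velocity",
    "mtu_force",
    "isometric_equilibrium",
    "force_length",
    "force_velocity_factor",
    "see_force",
    "pee_force",
]


@dataclass(frozen=True)
class MTUParams:
    """Constants of one muscle-tendon unit (SI units).

    ``see_linear_stiffness`` and ``pee_stiffness`` are normalized: force in
    units of ``f_max`` per unit tendon strain / per unit squared normalized
    fiber elongation.  ``serial_damping_coeff`` is normalized by
    ``f_max / v_ref`` with ``v_ref = hill_b_rel / hill_a_rel * l_ce_opt``
    (the maximal shortening velocity at full isometric force capacity).
    """

    name: str
    f_max: float                       # N
    l_ce_opt: float                    # m
    fl_width: float = 0.45             # width of the force-length bell
    hill_a_rel: float = 0.25
    hill_b_rel: float = 2.25           # 1/s
    eccentric_force_factor: float = 1.5    # asymptote of the eccentric branch
    eccentric_slope_factor: float = 2.0    # slope ratio ecc/conc at v = 0
    see_rest_length: float = 0.2       # m
    see_toe_strain: float = 0.015
    see_linear_stiffness: float = 30.8     # f_max per unit strain
    pee_slack_norm: float = 1.0        # fiber length (in l_ce_opt) where PEE engages
    pee_stiffness: float = 3.0         # f_max per unit (l_n - slack)^2
    serial_damping_coeff: float = 0.30
    activation_min: float = 0.005
    activation_rate_const: float = 11.3    # 1/s
    hatze_nu: float = 3.0
    hatze_rho: float = 6.0

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_ce_opt <= 0 or self.see_rest_length <= 0:
            raise ValueError(f"{self.name}: f_max, l_ce_opt, see_rest_length must be > 0")
        if not 0 < self.activation_min < 1:
            raise ValueError(f"{self.name}: activation_min must lie in (0, 1)")
        if self.hill_a_rel <= 0 or self.hill_b_rel <= 0:
            raise ValueError(f"{self.name}: Hill constants must be > 0")
        if self.eccentric_force_factor <= 1:
            raise ValueError(f"{self.name}: eccentric_force_factor must exceed 1")

    @property
    def v_ref(self) -> float:
        """Reference (maximal) shortening speed, m/s."""
        return self.hill_b_rel / self.hill_a_rel * self.l_ce_opt

    @property
    def serial_damping(self) -> float:
        """Dimensional SDE coefficient, N s/m."""
        return self.serial_damping_coeff * self.f_max / self.v_ref


@dataclass
class MTUState:
    """Dynamic state of one MTU: fiber length (m) and activity (0-1)."""

    l_ce: float
    activity: float


# --------------------------------------------------------------------------
# element curves
# --------------------------------------------------------------------------

def force_length(l_n: float, p: MTUParams) -> float:
    """Normalized isometric force-length curve (1 at the optimal length)."""
    return math.exp(-(((l_n - 1.0) / p.fl_width) ** 2))


def force_velocity_factor(v_n: float, f_iso: float, p: MTUParams) -> float:
    """Normalized CE force at normalized velocity ``v_n`` (shortening < 0).

    ``f_iso`` is the normalized isometric force (activity times
    force-length factor); the output is the full normalized CE force, not
    a multiplicative factor on it, because the Hill constants couple the
    two.
    """
    if v_n <= 0.0:
        num = f_iso * p.hill_b_rel + p.hill_a_rel * v_n
        if num <= 0.0:
            return 0.0
        return num / (p.hill_b_rel - v_n)
    n_ecc = p.eccentric_force_factor
    b_e = _ecc_b(f_iso, p)
    return n_ecc * f_iso - (n_ecc - 1.0) * f_iso * b_e / (b_e + v_n)


def _ecc_b(f_iso: float, p: MTUParams) -> float:
    """Curvature constant of the eccentric branch (continuity of slope)."""
    slope_con = (p.hill_a_rel + f_iso) / p.hill_b_rel
    return (p.eccentric_force_factor - 1.0) * f_iso / (
        p.eccentric_slope_factor * slope_con
    )


def see_force(l_see: float, p: MTUParams) -> float:
    """Tendon (SEE) force in N as a function of tendon length."""
    eps = (l_see - p.see_rest_length) / p.see_rest_length
    if eps <= 0.0:
        return 0.0
    k = p.see_linear_stiffness * p.f_max
    et = p.see_toe_strain
    if eps < et:
        return 0.5 * k / et * eps * eps
    return k * (eps - 0.5 * et)


def pee_force(l_ce: float, p: MTUParams) -> float:
    """Parallel elastic force in N (zero below the slack length)."""
    x = l_ce / p.l_ce_opt - p.pee_slack_norm
    if x <= 0.0:
        return 0.0
    return p.pee_stiffness * p.f_max * x * x


# --------------------------------------------------------------------------
# activation dynamics
# --------------------------------------------------------------------------

def activation_fixed_point(stimulation: float, l_n: float, p: MTUParams) -> float:
    """Steady-state activity for constant stimulation at fiber length ``l_n``."""
    rho = p.hatze_rho * max(l_n, 0.1)
    g = (rho * stimulation) ** p.hatze_nu
    return (p.activation_min + g) / (1.0 + g)


def activation_rate(activity: float, stimulation: float, l_ce: float,
                    p: MTUParams) -> float:
    """da/dt of the first-order, length-dependent activation dynamics."""
    a_inf = activation_fixed_point(stimulation, l_ce / p.l_ce_opt, p)
    return p.activation_rate_const * (a_inf - activity)


# --------------------------------------------------------------------------
# contraction dynamics: CE + PEE  =  SEE + SDE
# --------------------------------------------------------------------------

def _balance_residual(v_ce: float, l_ce: float, activity: float,
                      l_mtu: float, v_mtu: float, p: MTUParams) -> float:
    l_n = l_ce / p.l_ce_opt
    f_iso = activity * force_length(l_n, p)
    f_ce = p.f_max * force_velocity_factor(v_ce / p.l_ce_opt, f_iso, p)
    f_see = see_force(l_mtu - l_ce, p)
    f_sde = p.serial_damping * (v_mtu - v_ce)
    return f_ce + pee_force(l_ce, p) - f_see - f_sde


def fiber_velocity(l_ce: float, activity: float, l_mtu: float, v_mtu: float,
                   p: MTUParams) -> float:
    """Fiber velocity (m/s) from the internal CE+PEE vs SEE+SDE balance.

    Closed-form per Hill branch: substituting the hyperbolic force-velocity
    relation into the balance yields a quadratic in the normalized fiber
    velocity whose physically consistent root is selected by the sign of
    the residual at zero velocity.  Falls back to bracketed root-finding
    if the branch solution is inconsistent (e.g. zero serial damping with
    extreme loads).
    """
    l_n = l_ce / p.l_ce_opt
    f_iso = activity * force_length(l_n, p)
    # R is the force the CE + damping term must supply:
    #   F_ce(v) + d*v = F_see + d*v_mtu - F_pee =: R
    r = see_force(l_mtu - l_ce, p) + p.serial_damping * v_mtu - pee_force(l_ce, p)
    c = p.serial_damping * p.l_ce_opt      # damping per unit normalized velocity
    fm = p.f_max

    res0 = fm * f_iso - r                  # residual at v = 0
    if res0 == 0.0:
        return 0.0

    if res0 > 0.0:
        # concentric (shortening, v_n < 0)
        v_n0 = -f_iso * p.hill_b_rel / p.hill_a_rel   # zero-force velocity
        if c > 0.0:
            bq = -(fm * p.hill_a_rel + c * p.hill_b_rel + r)
            cq = -p.hill_b_rel * (fm * f_iso - r)
            disc = bq * bq - 4.0 * c * cq
            if disc >= 0.0:
                v_n = (-bq - math.sqrt(disc)) / (2.0 * c)
                if v_n >= v_n0:
                    return v_n * p.l_ce_opt
            # CE force clamped to zero: purely damped motion
            v = r / p.serial_damping
            if v / p.l_ce_opt <= v_n0:
                return v
        else:
            if r > 0.0:
                v_n = p.hill_b_rel * (r - fm * f_iso) / (fm * p.hill_a_rel + r)
                if v_n >= v_n0:
                    return v_n * p.l_ce_opt
    else:
        # eccentric (lengthening, v_n > 0)
        b_e = _ecc_b(f_iso, p)
        n_ecc = p.eccentric_force_factor
        if c > 0.0:
            bq = fm * n_ecc * f_iso + c * b_e - r
            cq = b_e * (fm * f_iso - r)
            disc = bq * bq - 4.0 * c * cq
            if disc >= 0.0:
                v_n = (-bq + math.sqrt(disc)) / (2.0 * c)
                if v_n >= 0.0:
                    return v_n * p.l_ce_opt
        else:
            f_asym = fm * n_ecc * f_iso
            if r < f_asym:
                v_n = b_e * (r - fm * f_iso) / (f_asym - r)
                return v_n * p.l_ce_opt

    return _fiber_velocity_bracketed(l_ce, activity, l_mtu, v_mtu, p)


def _fiber_velocity_bracketed(l_ce, activity, l_mtu, v_mtu, p: MTUParams):
    span = max(10.0 * p.v_ref, 10.0 * abs(v_mtu), 1.0)
    lo, hi = -span, span
    flo = _balance_residual(lo, l_ce, activity, l_mtu, v_mtu, p)
    fhi = _balance_residual(hi, l_ce, activity, l_mtu, v_mtu, p)
    tries = 0
    while flo * fhi > 0 and tries < 8:
        lo *= 4.0
        hi *= 4.0
        flo = _balance_residual(lo, l_ce, activity, l_mtu, v_mtu, p)
        fhi = _balance_residual(hi, l_ce, activity, l_mtu, v_mtu, p)
        tries += 1
    if flo * fhi > 0:
        raise ArithmeticError(
            f"{p.name}: no root of the internal force balance "
            f"(l_ce={l_ce:.4g}, a={activity:.4g}, l_mtu={l_mtu:.4g}, "
            f"v_mtu={v_mtu:.4g})"
        )
    return brentq(
        _balance_residual, lo, hi,
        args=(l_ce, activity, l_mtu, v_mtu, p), xtol=1e-12,
    )


def mtu_force(l_mtu: float, v_mtu: float, state: MTUState,
              p: MTUParams) -> tuple[float, float]:
    """Tendon force transmitted to bone (N) and fiber velocity (m/s)."""
    if l_mtu <= 0:
        raise ValueError(f"{p.name}: non-positive MTU length {l_mtu}")
    v_ce = fiber_velocity(state.l_ce, state.activity, l_mtu, v_mtu, p)
    force = see_force(l_mtu - state.l_ce, p) + p.serial_damping * (v_mtu - v_ce)
    return max(force, 0.0), v_ce


# --------------------------------------------------------------------------
# static equilibrium (initial conditions, equilibrium-point solving)
# --------------------------------------------------------------------------

def isometric_equilibrium(stimulation: float, l_mtu: float,
                          p: MTUParams) -> tuple[float, float, float]:
    """Static state under constant stimulation at fixed path length.

    Solves the coupled fixed point: activity at its stimulation- and
    length-dependent steady state, fiber length where the isometric
    CE + PEE force equals the SEE force.

    Returns ``(l_ce, activity, force)``.
    """

    def h(l_ce: float) -> float:
        l_n = l_ce / p.l_ce_opt
        a = activation_fixed_point(stimulation, l_n, p)
        f_act = p.f_max * a * force_length(l_n, p)
        return f_act + pee_force(l_ce, p) - see_force(l_mtu - l_ce, p)

    hi = l_mtu - p.see_rest_length          # slack tendon: h > 0
    if hi <= 0:
        raise ValueError(
            f"{p.name}: path length {l_mtu:.4g} shorter than tendon rest length"
        )
    lo = max(1e-4 * p.l_ce_opt, l_mtu - p.see_rest_length * (1.0 + 0.15))
    while h(lo) > 0 and lo > 1e-6:
        lo *= 0.5
    if h(lo) > 0 or h(hi) < 0:
        raise ArithmeticError(f"{p.name}: isometric equilibrium not bracketed")
    l_ce = brentq(h, lo, hi, xtol=1e-13)
    a = activation_fixed_point(stimulation, l_ce / p.l_ce_opt, p)
    force = see_force(l_mtu - l_ce, p)
    return l_ce, a, force
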