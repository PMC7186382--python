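"""Planar muscle-path routing with via-ellipse deflection.

Each muscle path runs from an origin fixed on the proximal (upper-arm)
segment to an insertion fixed on the distal (forearm) segment.  Between
them the path may be deflected by one or more ellipses rigidly attached to
either segment -- an obstacle-set representation of bony prominences and
joint capsules.  The taut path is the shortest origin-to-insertion route
that does not penetrate any ellipse: straight segments joined to
elliptical arcs at kink-free tangency points.

This construction gives, per joint angle,

* the muscle-tendon path length and (by tendon excursion) the moment arm,
* the resultant muscle-bone contact force at every deflection ellipse,
* the net force the muscle applies to the forearm, from which the elbow
  joint constraint force follows by a Newton-Euler balance.

Conventions: the world frame coincides with the (fixed, shoulder-locked)
upper-arm frame, shoulder at the origin, upper arm along +x, elbow at
``(upper_arm_length, 0)``.  The elbow angle ``phi`` is flexion-positive
and zero for a fully extended (straight) arm; the forearm x-axis points
from the elbow along the forearm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "DeflectionEllipse",
    "PathSpec",
    "RoutingResult",
    "solve_path",
    "moment_arm",
    "joint_loads",
    "RoutingTables",
]

_GAUSS_X, _GAUSS_W = leggauss(32)


def _cross2(a, b) -> float:
    """Scalar z-component of the 2-D cross product."""
    return float(a[0] * b[1] - a[1] * b[0])




class GeometryError(ValueError):
    """Raised when a path specification is geometrically inconsistent."""


@dataclass(frozen=True)
class DeflectionEllipse:
    """Ellipse obstacle attached to one segment (coordinates in its frame)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    owning_segment: str = "upper_arm"     # "upper_arm" | "forearm"
    angle: float = 0.0                    # orientation within the owning frame

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise GeometryError("ellipse semi-axes must be strictly positive")
        if self.owning_segment not in ("upper_arm", "forearm"):
            raise GeometryError(f"unknown segment {self.owning_segment!r}")


@dataclass(frozen=True)
class PathSpec:
    """Muscle path: origin (upper-arm frame), insertion (forearm frame)."""

    name: str
    origin_point: tuple[float, float]
    insertion_point: tuple[float, float]
    deflection_ellipses: tuple[DeflectionEllipse, ...] = ()


@dataclass
class RoutingResult:
    mtu_length: float
    moment_arm: float
    path_points: list          # world-frame polyline vertices (incl. tangent pts)
    wrapped: list              # per-ellipse flag
    tangent_points: list       # per-ellipse (T_in, T_out) or None
    contact_force_unit: list   # per-ellipse contact-force vector per unit tension
    forearm_force_unit: np.ndarray  # net force on forearm per unit tension
    path_deflected: bool = field(init=False)

    def __post_init__(self) -> None:
        self.path_deflected = any(self.wrapped)


# --------------------------------------------------------------------------
# frames
# --------------------------------------------------------------------------

def _forearm_frame(phi: float, upper_arm_length: float):
    e = np.array([upper_arm_length, 0.0])
    f = np.array([math.cos(phi), math.sin(phi)])       # forearm x-axis
    g = np.array([-math.sin(phi), math.cos(phi)])      # forearm y-axis
    return e, f, g


class _WorldEllipse:
    """Ellipse in world coordinates with its affine circle-space map."""

    def __init__(self, ell: DeflectionEllipse, phi: float, upper_arm_length: float):
        c = np.asarray(ell.center, dtype=float)
        psi = ell.angle
        if ell.owning_segment == "forearm":
            e, f, g = _forearm_frame(phi, upper_arm_length)
            self.center = e + c[0] * f + c[1] * g
            psi = psi + phi
        else:
            self.center = c
        self.a, self.b = ell.semi_axes
        cs, sn = math.cos(psi), math.sin(psi)
        self.rot = np.array([[cs, -sn], [sn, cs]])
        self.owning_segment = ell.owning_segment

    def to_circle(self, p: np.ndarray) -> np.ndarray:
        q = self.rot.T @ (p - self.center)
        return np.array([q[0] / self.a, q[1] / self.b])

    def boundary(self, theta: float) -> np.ndarray:
        q = np.array([self.a * math.cos(theta), self.b * math.sin(theta)])
        return self.center + self.rot @ q

    def boundary_tangent(self, theta: float, direction: float) -> np.ndarray:
        d = np.array([-self.a * math.sin(theta), self.b * math.cos(theta)])
        t = self.rot @ d
        return direction * t / np.linalg.norm(t)

    def arc_length(self, th0: float, th1: float) -> float:
        half = 0.5 * (th1 - th0)
        mid = 0.5 * (th1 + th0)
        th = mid + half * _GAUSS_X
        speed = np.sqrt((self.a * np.sin(th)) ** 2 + (self.b * np.cos(th)) ** 2)
        return abs(half) * float(np.dot(_GAUSS_W, speed))


# --------------------------------------------------------------------------
# single-obstacle wrap
# --------------------------------------------------------------------------

def _segment_clears(we: _WorldEllipse, p: np.ndarray, q: np.ndarray,
                    tol: float = 1e-12) -> bool:
    """True if segment p-q does not enter the open ellipse interior."""
    u, v = we.to_circle(p), we.to_circle(q)
    d = v - u
    dd = float(d @ d)
    if dd == 0.0:
        return float(u @ u) >= 1.0 - tol
    t = float(np.clip(-(u @ d) / dd, 0.0, 1.0))
    closest = u + t * d
    return float(closest @ closest) >= 1.0 - tol


def _circle_tangents(u: np.ndarray):
    """Tangent points on the unit circle seen from external point ``u``."""
    r2 = float(u @ u)
    if r2 <= 1.0:
        raise GeometryError("path endpoint inside a deflection ellipse")
    s = math.sqrt(r2 - 1.0)
    perp = np.array([-u[1], u[0]])
    return (u + s * perp) / r2, (u - s * perp) / r2


def _wrap_candidates(we: _WorldEllipse, p: np.ndarray, q: np.ndarray):
    """Kink-free taut wraps of the string p -> ellipse -> q.

    Enumerates tangent-point combinations and arc directions; a candidate
    is valid when the incoming and outgoing straight segments continue
    smoothly into the arc (no kink at either tangency).  Validity is
    checked in circle space, where it is affine-invariant.
    """
    up, uq = we.to_circle(p), we.to_circle(q)
    tps = _circle_tangents(up)
    tqs = _circle_tangents(uq)
    out = []
    for tp in tps:
        for tq in tqs:
            th_p = math.atan2(tp[1], tp[0])
            th_q = math.atan2(tq[1], tq[0])
            for direction in (1.0, -1.0):
                sweep = (th_q - th_p) % (2.0 * math.pi)
                if direction < 0:
                    sweep = sweep - 2.0 * math.pi
                if abs(sweep) < 1e-14:
                    continue
                # circle-space tangents of the arc at both junctions
                tan_p = direction * np.array([-math.sin(th_p), math.cos(th_p)])
                tan_q = direction * np.array([-math.sin(th_q), math.cos(th_q)])
                d_in = tp - up
                d_out = uq - tq
                if float(d_in @ tan_p) <= 0 or float(d_out @ tan_q) <= 0:
                    continue
                # cross products must vanish at a tangency (no kink)
                if abs(_cross2(d_in, tan_p)) > 1e-9 * np.linalg.norm(d_in):
                    continue
                if abs(_cross2(d_out, tan_q)) > 1e-9 * np.linalg.norm(d_out):
                    continue
                t_in = we.boundary(th_p)
                t_out = we.boundary(th_q)
                length = (
                    float(np.linalg.norm(t_in - p))
                    + we.arc_length(th_p, th_p + sweep)
                    + float(np.linalg.norm(q - t_out))
                )
                out.append((length, th_p, sweep, t_in, t_out))
    return out


def _solve_one(we: _WorldEllipse, p: np.ndarray, q: np.ndarray):
    """Shortest taut route p -> q around one ellipse.

    Returns ``(wrapped, t_in, t_out, arc_len)``.
    """
    if float(we.to_circle(p) @ we.to_circle(p)) < 1.0 or \
            float(we.to_circle(q) @ we.to_circle(q)) < 1.0:
        raise GeometryError("path anchor inside a deflection ellipse")
    if _segment_clears(we, p, q):
        return False, None, None, 0.0
    cands = _wrap_candidates(we, p, q)
    if not cands:
        raise GeometryError("no taut wrap found (degenerate geometry)")
    length, th_p, sweep, t_in, t_out = min(cands, key=lambda c: c[0])
    return True, t_in, t_out, we.arc_length(th_p, th_p + sweep)


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def solve_path(phi: float, spec: PathSpec, upper_arm_length: float) -> RoutingResult:
    """Taut muscle path at elbow angle ``phi`` (world-frame geometry).

    The path is resolved ellipse by ellipse (in the order given by the
    spec) with a fixed-point iteration over the tangency anchor points,
    which converges immediately for non-interacting obstacles and in a few
    sweeps otherwise.
    """
    e, f, g = _forearm_frame(phi, upper_arm_length)
    origin = np.asarray(spec.origin_point, dtype=float)
    ins_local = np.asarray(spec.insertion_point, dtype=float)
    insertion = e + ins_local[0] * f + ins_local[1] * g
    wells = [_WorldEllipse(el, phi, upper_arm_length)
             for el in spec.deflection_ellipses]

    n = len(wells)
    wrapped = [False] * n
    tps: list = [None] * n
    arc_lens = [0.0] * n

    for _ in range(25):
        prev = [(w, None if t is None else (t[0].copy(), t[1].copy()))
                for w, t in zip(wrapped, tps)]
        for k, we in enumerate(wells):
            left = origin
            for j in range(k - 1, -1, -1):
                if wrapped[j]:
                    left = tps[j][1]
                    break
            right = insertion
            for j in range(k + 1, n):
                if wrapped[j]:
                    right = tps[j][0]
                    break
            w, t_in, t_out, arc = _solve_one(we, left, right)
            wrapped[k] = w
            tps[k] = (t_in, t_out) if w else None
            arc_lens[k] = arc
        stable = True
        for (w0, t0), w1, t1 in zip(prev, wrapped, tps):
            if w0 != w1:
                stable = False
            elif t1 is not None and (
                np.linalg.norm(t0[0] - t1[0]) > 1e-12
                or np.linalg.norm(t0[1] - t1[1]) > 1e-12
            ):
                stable = False
        if stable:
            break

    # assemble the polyline and total length
    points = [origin]
    length = 0.0
    contact_units: list = [np.zeros(2)] * n
    for k in range(n):
        if not wrapped[k]:
            contact_units[k] = np.zeros(2)
            continue
        t_in, t_out = tps[k]
        length += float(np.linalg.norm(t_in - points[-1])) + arc_lens[k]
        points.extend([t_in, t_out])
    length += float(np.linalg.norm(insertion - points[-1]))
    points.append(insertion)

    # contact forces and the net force applied to the forearm (per unit tension)
    forearm_force = np.zeros(2)
    torque = 0.0
    idx = 1
    for k in range(n):
        if not wrapped[k]:
            continue
        t_in, t_out = tps[k]
        prev_pt = points[idx - 1]
        next_pt = points[idx + 2]
        u1 = (prev_pt - t_in) / np.linalg.norm(prev_pt - t_in)
        u2 = (next_pt - t_out) / np.linalg.norm(next_pt - t_out)
        contact = u1 + u2
        contact_units[k] = contact
        if wells[k].owning_segment == "forearm":
            forearm_force = forearm_force + contact
            torque += _cross2(t_in - e, u1) + _cross2(t_out - e, u2)
        idx += 2
    u_last = points[-2] - insertion
    u_last = u_last / np.linalg.norm(u_last)
    forearm_force = forearm_force + u_last
    torque += _cross2(insertion - e, u_last)

    return RoutingResult(
        mtu_length=length,
        moment_arm=torque,
        path_points=points,
        wrapped=wrapped,
        tangent_points=tps,
        contact_force_unit=contact_units,
        forearm_force_unit=forearm_force,
    )


def moment_arm(phi: float, spec: PathSpec, upper_arm_length: float) -> float:
    """Elbow moment arm (m), flexion-positive; equals -dL/dphi.

    Computed from the moment, about the elbow, of the path tension applied
    to the forearm (insertion pull plus contact forces of forearm-attached
    ellipses), which by the principle of virtual work equals the negative
    tendon excursion derivative.
    """
    return solve_path(phi, spec, upper_arm_length).moment_arm


def joint_loads(phi: float, forces, spec_list, upper_arm_length: float,
                com_acceleration=(0.0, 0.0), forearm_mass: float = 0.0):
    """Active elbow torque, elbow constraint force and contact forces.

    Parameters
    ----------
    forces : per-muscle tendon tension (N, non-negative).
    com_acceleration : world-frame acceleration of the forearm center of
        mass (for the Newton-Euler balance; zero for statics).
    Returns ``(active_torque, constraint_force, contact_forces)`` where
    ``contact_forces[i][k]`` is the contact-force vector at ellipse ``k``
    of muscle ``i``.
    """
    forces = np.asarray(forces, dtype=float)
    if np.any(forces < 0):
        raise ValueError("muscle forces must be non-negative")
    torque = 0.0
    muscle_force_on_forearm = np.zeros(2)
    contact_forces = []
    for f_i, spec in zip(forces, spec_list):
        res = solve_path(phi, spec, upper_arm_length)
        torque += f_i * res.moment_arm
        muscle_force_on_forearm += f_i * res.forearm_force_unit
        contact_forces.append([f_i * c for c in res.contact_force_unit])
    constraint = forearm_mass * np.asarray(com_acceleration, float) \
        - muscle_force_on_forearm
    return torque, constraint, contact_forces


# --------------------------------------------------------------------------
# cached geometry tables for fast simulation
# --------------------------------------------------------------------------

class _StackedSpline:
    """Cubic splines of several muscles on one shared uniform grid."""

    def __init__(self, x: np.ndarray, ys: np.ndarray):
        from scipy.interpolate import CubicSpline
        self.x = x
        self.splines = [CubicSpline(x, y) for y in ys]
        # stack piecewise-poly coefficients: (m, 4, n_intervals)
        self.c = np.stack([s.c for s in self.splines])
        self.x0 = x[0]
        self.h = x[1] - x[0]
        self.n = len(x) - 1

    def __call__(self, phi: float) -> np.ndarray:
        i = int((phi - self.x0) / self.h)
        i = 0 if i < 0 else (self.n - 1 if i >= self.n else i)
        dx = phi - self.x[i]
        c = self.c[:, :, i]
        return ((c[:, 0] * dx + c[:, 1]) * dx + c[:, 2]) * dx + c[:, 3]


class RoutingTables:
    """Per-muscle geometry precomputed on a dense elbow-angle grid.

    Path lengths, moment arms, forearm-applied force directions and
    per-ellipse contact-force vectors are smooth in the elbow angle
    (C1 at wrap touch/lift-off), so the forward dynamics samples cubic
    splines instead of re-solving the tangency geometry at every
    right-hand-side evaluation.
    """

    def __init__(self, specs, upper_arm_length: float,
                 phi_range: tuple[float, float], n_grid: int = 241):
        self.specs = list(specs)
        self.upper_arm_length = upper_arm_length
        self.phi_grid = np.linspace(phi_range[0], phi_range[1], n_grid)
        m = len(self.specs)
        lengths = np.empty((m, n_grid))
        arms = np.empty((m, n_grid))
        fx = np.empty((m, n_grid))
        fy = np.empty((m, n_grid))
        contact = []   # per muscle: list over ellipses of (2, n_grid)
        for i, spec in enumerate(self.specs):
            ncon = len(spec.deflection_ellipses)
            cvals = np.zeros((ncon, 2, n_grid))
            for j, phi in enumerate(self.phi_grid):
                res = solve_path(phi, spec, upper_arm_length)
                lengths[i, j] = res.mtu_length
                arms[i, j] = res.moment_arm
                fx[i, j], fy[i, j] = res.forearm_force_unit
                for k in range(ncon):
                    cvals[k, :, j] = res.contact_force_unit[k]
            contact.append(cvals)
        self.length = _StackedSpline(self.phi_grid, lengths)
        self.arm = _StackedSpline(self.phi_grid, arms)
        self.force_x = _StackedSpline(self.phi_grid, fx)
        self.force_y = _StackedSpline(self.phi_grid, fy)
        self._contact_splines = [
            [_StackedSpline(self.phi_grid, cvals[k]) for k in range(len(cvals))]
            for cvals in contact
        ]

    def lengths(self, phi: float) -> np.ndarray:
        return self.length(phi)

    def moment_arms(self, phi: float) -> np.ndarray:
        return self.arm(phi)

    def forearm_force_units(self, phi: float) -> np.ndarray:
        return np.stack([self.force_x(phi), self.force_y(phi)], axis=1)

    def contact_force_units(self, phi: float, muscle_index: int):
        return [s(phi) for s in self._contact_splines[muscle_index]]
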