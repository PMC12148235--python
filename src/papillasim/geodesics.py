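"""Geodesic trajectories on papilla, pin and user-supplied surfaces.

Geodesics are the paths of a tube that experiences no tangential torque:
the zero-guidance reference for pollen tube growth.  They are integrated in
chart coordinates from the second-order geodesic equation

    d2u^a/ds2 + Gamma^a_bc du^b/ds du^c/ds = 0,

with the Christoffel symbols built numerically from the embedding
derivatives (:func:`papillasim.geometry.metric_and_christoffel`).  On the
papilla the integrator switches automatically between the cylindrical
chart and a Cartesian pole-cap chart when the path approaches the pole,
where the cylindrical chart degenerates.

On any surface of revolution the Clairaut invariant R sin(phi) is an exact
first integral and serves as the primary correctness oracle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import (Chart, PapillaShape, PinShape, PoleCapChart,
                       metric_and_christoffel)
from .trajectory import Trajectory

#: chart-switch hysteresis for the papilla pole region (fractions of Lhead)
CAP_ENTER = 0.2
CAP_EXIT = 0.3


class NonRevolutionSurfaceError(TypeError):
    """Clairaut diagnostics require a surface of revolution."""


# --------------------------------------------------------------------------
# helpers: chart state <-> embedded state
# --------------------------------------------------------------------------

def chart_velocity_from_embedded(chart: Chart, point, v3) -> np.ndarray:
    """Chart velocities (du, dv) of an embedded tangent vector ``v3``."""
    Xu, Xv = chart.jacobian(point[0], point[1])
    g = np.array([[Xu @ Xu, Xu @ Xv], [Xu @ Xv, Xv @ Xv]])
    rhs = np.array([v3 @ Xu, v3 @ Xv])
    return np.linalg.solve(g, rhs)


def embedded_velocity(chart: Chart, point, vchart) -> np.ndarray:
    Xu, Xv = chart.jacobian(point[0], point[1])
    return vchart[0] * Xu + vchart[1] * Xv


def normalize_chart_velocity(chart: Chart, point, vchart) -> np.ndarray:
    v3 = embedded_velocity(chart, point, vchart)
    n = np.linalg.norm(v3)
    if n == 0:
        raise ValueError("zero initial velocity")
    return np.asarray(vchart, float) / n


def longitudinal_tangent(surface, chart: Chart, point) -> np.ndarray | None:
    """Unit surface tangent pointing towards the base, or None at the pole."""
    u, v = point
    if chart.kind == "cylindrical":
        Xu, Xv = chart.jacobian(u, v)
        return Xv / np.linalg.norm(Xv)              # increasing z -> base
    if chart.kind == "nurbs":
        Xu, Xv = chart.jacobian(u, v)
        return -Xu / np.linalg.norm(Xu)             # decreasing u1 -> base
    if chart.kind == "polecap":
        rho = math.hypot(u, v)
        if rho < 1e-9:
            return None
        Xu, Xv = chart.jacobian(u, v)
        t = (u * Xu + v * Xv) / rho                 # radially outward
        return t / np.linalg.norm(t)
    # generic chart: project the +z axis direction onto the tangent plane
    Xu, Xv = chart.jacobian(u, v)
    g = np.array([[Xu @ Xu, Xu @ Xv], [Xu @ Xv, Xv @ Xv]])
    comp = np.linalg.solve(g, np.array([Xu[2], Xv[2]]))
    t = comp[0] * Xu + comp[1] * Xv
    n = np.linalg.norm(t)
    return t / n if n > 1e-9 else None


def phi_from_tangent(surface, chart: Chart, point, t3) -> float:
    """Angle (deg) between a unit tangent and the base-ward direction."""
    t1 = longitudinal_tangent(surface, chart, point)
    if t1 is None:
        return float("nan")
    c = float(np.clip(t3 @ t1, -1.0, 1.0))
    return math.degrees(math.acos(c))


def initial_velocity_from_angle(surface, chart: Chart, point,
                                phi_deg: float) -> np.ndarray:
    """Unit chart velocity at ``point`` making angle phi with the
    longitudinal direction (phi = 0 towards the base, 90 circumferential)."""
    t1 = longitudinal_tangent(surface, chart, point)
    if t1 is None:
        raise ValueError("longitudinal direction undefined at the pole")
    X = chart.embedding(point[0], point[1])
    theta = math.atan2(X[1], X[0])
    t2 = np.array([-math.sin(theta), math.cos(theta), 0.0])
    phi = math.radians(phi_deg)
    v3 = math.cos(phi) * t1 + math.sin(phi) * t2
    # project onto the tangent plane (t1, t2 are both tangent already)
    vch = chart_velocity_from_embedded(chart, point, v3)
    return normalize_chart_velocity(chart, point, vch)


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def _geodesic_rhs(chart: Chart):
    def rhs(s, y):
        patch = metric_and_christoffel(chart, (y[0], y[1]))
        du = y[2:]
        acc = -np.einsum("abc,b,c->a", patch.christoffel, du, du)
        return np.hstack([du, acc])
    return rhs


def _segment(chart, y0, s0, s_max, events):
    sol = solve_ivp(_geodesic_rhs(chart), (s0, s_max), y0, method="RK45",
                    rtol=1e-8, atol=1e-10, dense_output=True, events=events)
    if sol.status == -1:
        raise RuntimeError(f"geodesic integration failed: {sol.message}")
    return sol


def integrate_geodesic(surface, P0, t0=None, *, phi0_deg: float | None = None,
                       s_max: float | None = None, ds: float | None = None,
                       z_stop: float | None = None) -> Trajectory:
    """Shoot a geodesic from chart point ``P0``.

    Parameters
    ----------
    surface : PapillaShape | PinShape | Chart
        For a papilla, ``P0 = (theta, z)`` and chart switching across the
        pole cap is automatic.  For a pin, ``P0 = (u1, u2)``.  A bare chart
        (e.g. a cylinder or sphere used as an oracle) is integrated as-is.
    t0 : chart velocity, normalized internally to unit embedded speed.
    phi0_deg : alternative to ``t0``: initial angle to the longitudinal
        direction (surfaces of revolution only).
    s_max : maximum arc length; default 20x the surface height.  Paths
        that exhaust it (e.g. trapped above a narrow neck) are flagged
        ``confined``.
    z_stop : termination height (papilla: default ``z_base``).
    """
    if isinstance(surface, PapillaShape):
        return _integrate_papilla(surface, P0, t0, phi0_deg, s_max, ds,
                                  z_stop)
    if isinstance(surface, PinShape):
        return _integrate_pin(surface, P0, t0, phi0_deg, s_max, ds)
    if isinstance(surface, Chart):
        return _integrate_plain(surface, P0, t0, phi0_deg, s_max, ds)
    raise TypeError(f"unsupported surface {type(surface)!r}")


def _finish(surface, samples, outcome, meta) -> Trajectory:
    s, pts, tans, phis = samples
    return Trajectory(s=np.asarray(s), points=np.asarray(pts),
                      tangents=np.asarray(tans), phi=np.asarray(phis),
                      outcome=outcome, metadata=meta)


def _sample_segment(surface, chart, sol, s_grid, out):
    s_list, pts, tans, phis = out
    for si in s_grid:
        y = sol.sol(si)
        p = (y[0], y[1])
        t3 = embedded_velocity(chart, p, y[2:])
        nrm = np.linalg.norm(t3)
        if nrm > 0:
            t3 = t3 / nrm
        s_list.append(si)
        pts.append(chart.embedding(*p))
        tans.append(t3)
        phis.append(phi_from_tangent(surface, chart, p, t3))


def _integrate_plain(chart, P0, t0, phi0_deg, s_max, ds):
    if s_max is None:
        s_max = 100.0
    if ds is None:
        ds = s_max / 2000.0
    if t0 is None:
        raise ValueError("t0 required for a bare chart")
    y0 = np.hstack([P0, normalize_chart_velocity(chart, P0, t0)])
    sol = _segment(chart, y0, 0.0, s_max, events=None)
    out = ([], [], [], [])
    _sample_segment(None, chart, sol, np.arange(0.0, sol.t[-1] + ds / 2, ds),
                    out)
    return _finish(None, out, "max_length", {"chart": chart.kind})


def _integrate_pin(pin: PinShape, P0, t0, phi0_deg, s_max, ds):
    chart = pin.chart()
    if s_max is None:
        s_max = 20.0 * pin.H
    if ds is None:
        ds = pin.H / 400.0
    if t0 is None:
        t0 = initial_velocity_from_angle(pin, chart, P0, phi0_deg)
    y0 = np.hstack([P0, normalize_chart_velocity(chart, P0, t0)])

    def at_base(s, y):
        return y[0]
    at_base.terminal = True
    at_base.direction = -1

    def at_pole(s, y):
        return y[0] - (1.0 - 1e-3)
    at_pole.terminal = True
    at_pole.direction = 1

    sol = _segment(chart, y0, 0.0, s_max, events=[at_base, at_pole])
    out = ([], [], [], [])
    _sample_segment(pin, chart, sol, np.arange(0.0, sol.t[-1], ds), out)
    # include the exact endpoint
    _sample_segment(pin, chart, sol, [sol.t[-1]], out)
    if sol.t_events[0].size:
        outcome = "reached_base"
    elif sol.t_events[1].size:
        outcome = "confined"   # ran into the pole chart singularity
    else:
        outcome = "confined"
    traj = _finish(pin, out, outcome,
                   {"surface": "pin", "W": pin.W, "H": pin.H,
                    "D": pin.neck_diameter()})
    if outcome == "reached_base":
        dtheta = traj.azimuth_unwrapped()
        traj.turn_number = abs(dtheta[-1] - dtheta[0]) / (2 * math.pi)
    else:
        traj.turn_number = np.inf
    return traj


def _integrate_papilla(shape: PapillaShape, P0, t0, phi0_deg, s_max, ds,
                       z_stop):
    if z_stop is None:
        z_stop = shape.z_base
    if s_max is None:
        s_max = 20.0 * shape.z_base
    if ds is None:
        ds = 0.1
    cyl = shape.cylindrical_chart()
    cap = shape.polecap_chart()
    z_in = CAP_ENTER * shape.Lhead
    z_out = CAP_EXIT * shape.Lhead

    theta0, z0 = P0
    if z0 < z_out:
        chart = cap
        R0 = shape.radius(z0)[0]
        point = (R0 * math.cos(theta0), R0 * math.sin(theta0))
    else:
        chart = cyl
        point = (theta0, z0)
    if t0 is None:
        vch = initial_velocity_from_angle(shape, chart, point, phi0_deg)
    else:
        if chart is cap:
            raise ValueError("chart velocities only supported for starts in "
                             "the cylindrical region; use phi0_deg")
        vch = normalize_chart_velocity(chart, point, np.asarray(t0, float))

    out = ([], [], [], [])
    s = 0.0
    outcome = "confined"
    y = np.hstack([point, vch])
    for _ in range(200):          # generous chart-switch budget
        if chart is cyl:
            def reach_base(t, yy):
                return yy[1] - z_stop
            reach_base.terminal = True
            reach_base.direction = 1

            def enter_cap(t, yy):
                return yy[1] - z_in
            enter_cap.terminal = True
            enter_cap.direction = -1
            sol = _segment(cyl, y, s, s_max, [reach_base, enter_cap])
            s0 = math.ceil((s - 1e-12) / ds) * ds   # stay on the global
            grid = np.arange(s0, sol.t[-1], ds)      # ds-aligned grid
            _sample_segment(shape, cyl, sol, grid, out)
            s_end = sol.t[-1]
            if sol.t_events[0].size:        # reached the base
                _sample_segment(shape, cyl, sol, [s_end], out)
                outcome = "reached_base"
                break
            if sol.t_events[1].size:        # switch to the pole cap
                yy = sol.sol(s_end)
                p3 = cyl.embedding(yy[0], yy[1])
                v3 = embedded_velocity(cyl, yy[:2], yy[2:])
                pt = (p3[0], p3[1])
                vch = chart_velocity_from_embedded(cap, pt, v3)
                y = np.hstack([pt, vch])
                chart = cap
                s = s_end
                continue
            _sample_segment(shape, cyl, sol, [s_end], out)
            outcome = "confined"            # ran out of arc length
            break
        else:
            def leave_cap(t, yy):
                return cap.height(yy[0], yy[1]) - z_out
            leave_cap.terminal = True
            leave_cap.direction = 1
            sol = _segment(cap, y, s, s_max, [leave_cap])
            s0 = math.ceil((s - 1e-12) / ds) * ds   # stay on the global
            grid = np.arange(s0, sol.t[-1], ds)      # ds-aligned grid
            _sample_segment(shape, cap, sol, grid, out)
            s_end = sol.t[-1]
            if sol.t_events[0].size:
                yy = sol.sol(s_end)
                p3 = cap.embedding(yy[0], yy[1])
                v3 = embedded_velocity(cap, yy[:2], yy[2:])
                theta = math.atan2(p3[1], p3[0])
                pt = (theta, p3[2])
                vch = chart_velocity_from_embedded(cyl, pt, v3)
                y = np.hstack([pt, vch])
                chart = cyl
                s = s_end
                continue
            _sample_segment(shape, cap, sol, [s_end], out)
            outcome = "confined"
            break

    traj = _finish(shape, out, outcome,
                   {"surface": "papilla",
                    "genotype": shape.descriptors.genotype,
                    "P0": [float(theta0), float(z0)],
                    "phi0_deg": phi0_deg})
    if outcome == "reached_base":
        dtheta = traj.azimuth_unwrapped()
        traj.turn_number = abs(dtheta[-1] - dtheta[0]) / (2 * math.pi)
    else:
        traj.turn_number = np.inf
    return traj


# --------------------------------------------------------------------------
# Clairaut diagnostics
# --------------------------------------------------------------------------

def clairaut_invariant(traj: Trajectory) -> np.ndarray:
    """Series of R sin(phi) along a trajectory on a surface of revolution.

    Computed chart-independently as the axial angular momentum
    x v_y - y v_x of the unit tangent; constant along any geodesic
    (Clairaut's relation).
    """
    if traj.metadata.get("revolution", True) is False:
        raise NonRevolutionSurfaceError(
            "Clairaut invariant requires a surface of revolution")
    return traj.angular_momentum()


def clairaut_deviation(traj: Trajectory) -> float:
    """Max deviation of R sin(phi), relative to its starting magnitude
    (absolute deviation for meridians, where the invariant is zero)."""
    inv = clairaut_invariant(traj)
    scale = max(abs(float(inv[0])), 1e-12)
    dev = float(np.max(np.abs(inv - inv[0])))
    return dev / scale if abs(inv[0]) > 1e-9 else dev
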