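"""Guided, self-avoiding pollen tube growth on the papilla surface.

The tube is an inextensible filament with bending rigidity chi growing at
its tip, constrained to the papilla surface.  In the cylindrical chart the
tip state is (theta, z, phi), where phi is the angle between the growth
direction and the base-ward longitudinal tangent, and evolves as

    dtheta/ds = sin(phi) / R
    dz/ds     = cos(phi) / sqrt(1 + R'^2)
    dphi/ds   = -sin(phi) R' / (R sqrt(1 + R'^2)) - (mu / ell) sin(2 phi)

with the torque term active only below the guidance activation height
(z > z_c).  With mu = 0 the equations describe a geodesic (R sin phi is
then conserved).  Near the pole the integrator switches to the Cartesian
pole-cap chart.

Self-avoidance: the deposited tube is a chain of spheres and cylinders
(capsules) of radius r that the advancing tip cannot penetrate.  When the
momentum-conservation direction would penetrate, the growth direction is
deflected within the local tangent plane to the feasible direction of
minimal contact-plus-bending cost; if no direction is feasible the tube is
caged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import PapillaShape, PoleCapChart
from .geodesics import CAP_ENTER, CAP_EXIT
from .trajectory import TUBE_RADIUS, Trajectory

#: reference length of the adimensional guidance (um): the tube radius scale
GUIDANCE_LENGTH = 2.5
#: nominal tube bending rigidity (MPa um^4); shared with wall_mechanics so
#: both modules express the guidance on a single mu scale
CHI_NOMINAL = 500.0


@dataclass(frozen=True)
class GuidanceParams:
    """Mechanical guidance parameters.

    mu : adimensional guidance strength mu = m*ell/chi (>= 0)
    ell : reference length (um), the pollen tube radius scale
    chi : tube bending rigidity (MPa um^4); only the ratio mu/ell enters
        the trajectory equations
    z_c : activation height (um); the torque acts for z > z_c only.
        ``None`` means "use the shape's z_c" (default: Lhead).
    """

    mu: float = 0.0
    ell: float = GUIDANCE_LENGTH
    chi: float = CHI_NOMINAL
    z_c: float | None = None

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    @property
    def m(self) -> float:
        """Torque magnitude m = mu * chi / ell."""
        return self.mu * self.chi / self.ell


def alignment_torque(phi_deg: float, z: float, params: GuidanceParams,
                     z_c: float | None = None) -> float:
    """External alignment torque M = m sin(2 phi) for z > z_c, else 0.

    The sign convention is such that 0 < phi < 90 deg relaxes towards
    phi = 0 (base-ward growth) and 90 < phi < 180 deg towards phi = 180
    (pole-ward growth); growth along the circumferential direction
    (phi = 90 deg) experiences no torque.
    """
    zc = params.z_c if z_c is None else z_c
    if zc is None:
        raise ValueError("z_c undefined; pass z_c or set it on params")
    if z <= zc:
        return 0.0
    return params.m * math.sin(2.0 * math.radians(phi_deg))


# --------------------------------------------------------------------------
# collision helpers
# --------------------------------------------------------------------------

def segment_distances(p: np.ndarray, A: np.ndarray, B: np.ndarray
                      ) -> np.ndarray:
    """Exact distances from point ``p`` to segments A[i]->B[i]."""
    AB = B - A
    ab2 = np.einsum("ij,ij->i", AB, AB)
    ap = p - A
    t = np.clip(np.einsum("ij,ij->i", ap, AB) / np.maximum(ab2, 1e-30),
                0.0, 1.0)
    closest = A + t[:, None] * AB
    d = p - closest
    return np.sqrt(np.einsum("ij,ij->i", d, d))


def detect_collision(candidate: np.ndarray, path: np.ndarray, r: float,
                     window: int = 0) -> tuple[bool, float]:
    """Does a tip sphere at ``candidate`` penetrate the capsule chain?

    ``path`` is the (N, 3) polyline of deposited tube positions; the last
    ``window`` segments (the tube's own neck) are excluded.  Returns
    (penetrates, min_distance); penetration means distance < 2 r.
    """
    n_seg = len(path) - 1 - window
    if n_seg < 1:
        return False, np.inf
    d = segment_distances(np.asarray(candidate, float),
                          path[:n_seg], path[1:n_seg + 1])
    dmin = float(d.min())
    return dmin < 2.0 * r, dmin


def growth_window(r: float = TUBE_RADIUS, ds: float = 0.1) -> int:
    """Self-adjacency window: number of most recent path segments excluded
    from the tip's collision test.

    The base value ceil(2r/ds)+2 (the arc a straight tube needs before its
    tip clears its own neck) is extended by a 1 um arc margin: on a curved
    surface, and while sliding along a contact, the path bends at radii
    down to ~2r, so the chord across exactly 2r of arc falls slightly
    short of 2r and the bare window would pin the tip against its own neck.
    """
    return math.ceil((2.0 * r + 1.0) / ds) + 2


def audit_window(r: float = TUBE_RADIUS, ds: float = 0.1) -> int:
    """Window for post-hoc clearance audits of stored trajectories; a few
    segments wider than :func:`growth_window` so that every audited
    point/segment pair was enforced during growth."""
    return growth_window(r, ds) + 4


#: maximum one-step deflection at a contact (deg): the tip may turn up to
#: perpendicular to its growth direction but never reverses onto itself
MAX_DEFLECTION_DEG = 90.0


# --------------------------------------------------------------------------
# the grower
# --------------------------------------------------------------------------

class CagedError(RuntimeError):
    pass


class _Grower:
    """Stateful fixed-step integrator with excluded-volume resolution."""

    def __init__(self, shape: PapillaShape, params: GuidanceParams, *,
                 ds: float, r: float, z_base: float, max_length: float,
                 obstacles=None, contact_tol: float = 1e-6):
        self.shape = shape
        self.params = params
        self.ds = ds
        self.r = r
        self.z_base = z_base
        self.max_length = max_length
        self.cap = PoleCapChart(shape)
        self.z_in = CAP_ENTER * shape.Lhead
        self.z_out = CAP_EXIT * shape.Lhead
        self.z_c = params.z_c if params.z_c is not None else shape.z_c
        if self.z_c < self.z_out:
            raise ValueError("z_c below the pole-cap chart region is not "
                             "supported (guidance must vanish near the pole)")
        self.mu_over_ell = params.mu / params.ell
        self.clear = 2.0 * r - contact_tol
        self.obstacles = [np.asarray(o, float) for o in (obstacles or [])]
        self.window = growth_window(r, ds)
        nmax = int(max_length / ds) + 4
        self.P = np.empty((nmax, 3))
        self.T = np.empty((nmax, 3))
        self.phi_rec = np.empty(nmax)
        self.theta_rec = np.empty(nmax)
        self.n = 0
        self.contacts = 0

    # ---- chart dynamics --------------------------------------------------

    def _rhs_cyl(self, th, z, ph):
        R, R1, _ = self.shape.radius_scalar(z)
        g = math.sqrt(1.0 + R1 * R1)
        sp, cp = math.sin(ph), math.cos(ph)
        dph = -sp * R1 / (R * g)
        if z > self.z_c and self.mu_over_ell:
            dph -= self.mu_over_ell * math.sin(2.0 * ph)
        return sp / R, cp / g, dph

    def _step_cyl(self, st, h):
        th, z, ph = st
        k1 = self._rhs_cyl(th, z, ph)
        k2 = self._rhs_cyl(th + 0.5 * h * k1[0], z + 0.5 * h * k1[1],
                           ph + 0.5 * h * k1[2])
        k3 = self._rhs_cyl(th + 0.5 * h * k2[0], z + 0.5 * h * k2[1],
                           ph + 0.5 * h * k2[2])
        k4 = self._rhs_cyl(th + h * k3[0], z + h * k3[1], ph + h * k3[2])
        return (th + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
                z + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
                ph + h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]))

    def _rhs_cap(self, x, y, vx, vy):
        cap = self.cap
        g1, g2 = cap._derivs(x, y)
        fx, fy = 2 * x * g1, 2 * y * g1
        fxx, fxy, fyy = 2 * g1 + 4 * x * x * g2, 4 * x * y * g2, \
            2 * g1 + 4 * y * y * g2
        W2 = 1.0 + fx * fx + fy * fy
        S = (fxx * vx * vx + 2 * fxy * vx * vy + fyy * vy * vy) / W2
        return vx, vy, -fx * S, -fy * S

    def _step_cap(self, st, h):
        x, y, vx, vy = st
        k1 = self._rhs_cap(x, y, vx, vy)
        k2 = self._rhs_cap(x + 0.5 * h * k1[0], y + 0.5 * h * k1[1],
                           vx + 0.5 * h * k1[2], vy + 0.5 * h * k1[3])
        k3 = self._rhs_cap(x + 0.5 * h * k2[0], y + 0.5 * h * k2[1],
                           vx + 0.5 * h * k2[2], vy + 0.5 * h * k2[3])
        k4 = self._rhs_cap(x + h * k3[0], y + h * k3[1],
                           vx + h * k3[2], vy + h * k3[3])
        x2 = x + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y2 = y + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        vx2 = vx + h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        vy2 = vy + h / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        # renormalise to unit embedded speed
        g1, _ = self.cap._derivs(x2, y2)
        vz = 2 * (x2 * vx2 + y2 * vy2) * g1
        sp = math.sqrt(vx2 * vx2 + vy2 * vy2 + vz * vz)
        return x2, y2, vx2 / sp, vy2 / sp

    # ---- embeddings ------------------------------------------------------

    def _embed_cyl(self, st):
        th, z, _ = st
        R = self.shape.radius_scalar(z)[0]
        return np.array([R * math.cos(th), R * math.sin(th), z])

    def _embed_cap(self, st):
        x, y = st[0], st[1]
        return np.array([x, y, self.cap.height(x, y)])

    def _tangent_cyl(self, st):
        th, z, ph = st
        _, R1, _ = self.shape.radius_scalar(z)
        g = math.sqrt(1.0 + R1 * R1)
        sp, cp = math.sin(ph), math.cos(ph)
        ct, stn = math.cos(th), math.sin(th)
        return np.array([-sp * stn + cp * R1 * ct / g,
                         sp * ct + cp * R1 * stn / g, cp / g])

    def _tangent_cap(self, st):
        x, y, vx, vy = st
        g1, _ = self.cap._derivs(x, y)
        t3 = np.array([vx, vy, vx * 2 * x * g1 + vy * 2 * y * g1])
        return t3 / np.linalg.norm(t3)

    # ---- collision -------------------------------------------------------

    def _blocked(self, p: np.ndarray) -> bool:
        n_seg = self.n - 1 - self.window
        if n_seg >= 1:
            zs = self.P[:n_seg + 1, 2]
            # only capsules whose z-range comes near the tip can collide
            near = np.flatnonzero(
                (np.minimum(zs[:-1], zs[1:]) < p[2] + self.clear + self.ds)
                & (np.maximum(zs[:-1], zs[1:]) > p[2] - self.clear - self.ds))
            if near.size:
                d = segment_distances(p, self.P[near], self.P[near + 1])
                if d.min() < self.clear:
                    return True
        for obs in self.obstacles:
            if len(obs) >= 2:
                d = segment_distances(p, obs[:-1], obs[1:])
                if d.min() < self.clear:
                    return True
        return False

    # ---- candidate generation for contact resolution ---------------------

    def _candidate(self, chart, st, d_rad):
        """One growth step with the initial heading deflected by d_rad."""
        if chart == "cyl":
            st2 = self._step_cyl((st[0], st[1], st[2] + d_rad), self.ds)
            return st2, self._embed_cyl(st2)
        x, y, vx, vy = st
        # rotate the embedded tangent about the surface normal
        cap = self.cap
        g1, _ = cap._derivs(x, y)
        fx, fy = 2 * x * g1, 2 * y * g1
        t3 = np.array([vx, vy, vx * fx + vy * fy])
        nrm = np.array([-fx, -fy, 1.0])
        nrm /= np.linalg.norm(nrm)
        t3 = t3 / np.linalg.norm(t3)
        t3r = math.cos(d_rad) * t3 + math.sin(d_rad) * np.cross(nrm, t3)
        st2 = self._step_cap((x, y, t3r[0], t3r[1]), self.ds)
        return st2, self._embed_cap(st2)

    def resolve_contact(self, chart, st, scan_deg: float = 1.0):
        """Feasible deflected direction of minimal bending-plus-guidance
        cost; raises :class:`CagedError` when the tip is fully enclosed."""
        best = None
        for k in range(1, int(MAX_DEFLECTION_DEG / scan_deg) + 1):
            for sgn in (1.0, -1.0):
                d = math.radians(sgn * k * scan_deg)
                st2, p = self._candidate(chart, st, d)
                if not self._blocked(p):
                    cost = d * d
                    if chart == "cyl" and st2[1] > self.z_c:
                        # guidance potential breaks left/right ties
                        cost -= self.ds * self.mu_over_ell * \
                            math.cos(2.0 * st2[2])
                    if best is None or cost < best[0]:
                        best = (cost, st2, p)
            if best is not None:
                return best[1], best[2]
        raise CagedError("no feasible growth direction")

    # ---- bookkeeping -----------------------------------------------------

    def _push(self, p, t3, phi_deg, theta_cont):
        self.P[self.n] = p
        self.T[self.n] = t3
        self.phi_rec[self.n] = phi_deg
        self.theta_rec[self.n] = theta_cont
        self.n += 1


def _phi_of_cap_state(grower, st) -> float:
    x, y, vx, vy = st
    rho = math.hypot(x, y)
    if rho < 1e-9:
        return float("nan")
    g1, _ = grower.cap._derivs(x, y)
    fx, fy = 2 * x * g1, 2 * y * g1
    t3 = np.array([vx, vy, vx * fx + vy * fy])
    t3 /= np.linalg.norm(t3)
    e1 = np.array([x / rho, y / rho, (x * fx + y * fy) / rho])
    e1 /= np.linalg.norm(e1)
    return math.degrees(math.acos(max(-1.0, min(1.0, float(t3 @ e1)))))


def grow_tube(shape: PapillaShape, z0: float, phi0_deg: float,
              params: GuidanceParams | None = None, *,
              theta0: float = 0.0, ds: float = 0.1,
              tube_radius: float = TUBE_RADIUS,
              z_base: float | None = None,
              max_length_factor: float = 15.0,
              s_max: float | None = None,
              obstacles=None) -> Trajectory:
    """Simulate one pollen tube from landing position ``z0`` (um below the
    pole) and emergence angle ``phi0_deg`` (0 = base-ward, 90 =
    circumferential, 180 = pole-ward; angles in [180, 360) are mirrored).

    Returns a :class:`Trajectory` whose ``outcome`` is ``reached_base``
    (with its turn number), ``caged`` (trapped by its own excluded volume
    or exhausted ``max_length_factor * z_base`` of arc length) or
    ``max_length`` (an explicit ``s_max`` was hit first).
    """
    params = params or GuidanceParams()
    if z_base is None:
        z_base = shape.z_base
    if not 0 < z0 <= 2.0 * shape.Lhead + 1e-9:
        raise ValueError("z0 must lie in (0, 2*Lhead] (pollen grains attach "
                         "to the papilla head region)")
    phi0_deg = phi0_deg % 360.0
    if phi0_deg > 180.0:       # mirror symmetry of the model
        phi0_deg = 360.0 - phi0_deg

    max_length = max_length_factor * z_base
    hard_cap = s_max if s_max is not None else max_length
    g = _Grower(shape, params, ds=ds, r=tube_radius, z_base=z_base,
                max_length=max(max_length, hard_cap), obstacles=obstacles)

    # ---- initial state ---------------------------------------------------
    phi0 = math.radians(phi0_deg)
    if z0 >= g.z_out:
        chart = "cyl"
        st = (theta0, z0, phi0)
        p = g._embed_cyl(st)
        theta_cont = theta0
        g._push(p, g._tangent_cyl(st), phi0_deg, theta_cont)
    else:
        chart = "cap"
        R0 = shape.radius_scalar(z0)[0]
        x, y = R0 * math.cos(theta0), R0 * math.sin(theta0)
        g1, _ = g.cap._derivs(x, y)
        fx, fy = 2 * x * g1, 2 * y * g1
        rho = math.hypot(x, y)
        e1 = np.array([x / rho, y / rho, (x * fx + y * fy) / rho])
        e1 /= np.linalg.norm(e1)
        e2 = np.array([-math.sin(theta0), math.cos(theta0), 0.0])
        t3 = math.cos(phi0) * e1 + math.sin(phi0) * e2
        st = (x, y, t3[0], t3[1])
        # renormalise chart velocity to unit embedded speed
        vz = t3[0] * fx + t3[1] * fy
        sp = math.sqrt(t3[0] ** 2 + t3[1] ** 2 + vz ** 2)
        st = (x, y, t3[0] / sp, t3[1] / sp)
        p = g._embed_cap(st)
        theta_cont = theta0
        g._push(p, g._tangent_cap(st), phi0_deg, theta_cont)

    outcome = "caged"
    s = 0.0
    turn = math.inf
    first_contact_s = math.inf
    while s < hard_cap - 0.5 * ds:
        if chart == "cyl":
            st2 = g._step_cyl(st, ds)
            p2 = g._embed_cyl(st2)
        else:
            st2 = g._step_cap(st, ds)
            p2 = g._embed_cap(st2)
        if g._blocked(p2):
            if g.contacts == 0:
                first_contact_s = s + ds
            g.contacts += 1
            try:
                st2, p2 = g.resolve_contact(chart, st)
            except CagedError:
                outcome = "caged"
                break
        s += ds
        if chart == "cyl":
            theta_cont = st2[0]
            phi_deg = math.degrees(abs(st2[2]))
            z2 = st2[1]
        else:
            th_new = math.atan2(p2[1], p2[0])
            dtheta = (th_new - theta_cont + math.pi) % (2 * math.pi) - math.pi
            theta_cont = theta_cont + dtheta
            phi_deg = _phi_of_cap_state(g, st2)
            z2 = p2[2]

        t3_new = g._tangent_cyl(st2) if chart == "cyl" else \
            g._tangent_cap(st2)

        if z2 >= z_base:                       # crossed the observable base
            z1 = g.P[g.n - 1, 2]
            f = (z_base - z1) / max(z2 - z1, 1e-30)
            th_cross = g.theta_rec[g.n - 1] + f * \
                (theta_cont - g.theta_rec[g.n - 1])
            Rb = shape.radius_scalar(z_base)[0]
            p_cross = np.array([Rb * math.cos(th_cross),
                                Rb * math.sin(th_cross), z_base])
            g._push(p_cross, t3_new, phi_deg, th_cross)
            turn = abs(th_cross - g.theta_rec[0]) / (2 * math.pi)
            outcome = "reached_base"
            break

        g._push(p2, t3_new, phi_deg, theta_cont)
        st = st2

        # chart switching with hysteresis
        if chart == "cyl" and st[1] < g.z_in:
            th, z, ph = st
            R = shape.radius_scalar(z)[0]
            x, y = R * math.cos(th), R * math.sin(th)
            # embedded tangent of the cylindrical state
            R_, R1, _ = shape.radius_scalar(z)
            gg = math.sqrt(1 + R1 * R1)
            sp_, cp_ = math.sin(ph), math.cos(ph)
            t3 = (sp_ / R_) * np.array([-R_ * math.sin(th),
                                        R_ * math.cos(th), 0.0]) + \
                (cp_ / gg) * np.array([R1 * math.cos(th),
                                       R1 * math.sin(th), 1.0])
            st = (x, y, t3[0], t3[1])
            g1_, _ = g.cap._derivs(x, y)
            vz = t3[0] * 2 * x * g1_ + t3[1] * 2 * y * g1_
            spn = math.sqrt(t3[0] ** 2 + t3[1] ** 2 + vz ** 2)
            st = (x, y, t3[0] / spn, t3[1] / spn)
            chart = "cap"
        elif chart == "cap":
            z_now = g.cap.height(st[0], st[1])
            if z_now > g.z_out:
                x, y, vx, vy = st
                th = math.atan2(y, x)
                g1_, _ = g.cap._derivs(x, y)
                vz = vx * 2 * x * g1_ + vy * 2 * y * g1_
                t3 = np.array([vx, vy, vz])
                t3 /= np.linalg.norm(t3)
                R_, R1, _ = shape.radius_scalar(z_now)
                gg = math.sqrt(1 + R1 * R1)
                e1 = np.array([R1 * math.cos(th), R1 * math.sin(th),
                               1.0]) / gg
                e2 = np.array([-math.sin(th), math.cos(th), 0.0])
                ph = math.atan2(float(t3 @ e2), float(t3 @ e1))
                st = (theta_cont, z_now, ph)
                chart = "cyl"
    else:
        outcome = "max_length" if s_max is not None else "caged"

    if outcome == "caged":
        turn = math.inf

    n = g.n
    pts = g.P[:n].copy()
    phis = g.phi_rec[:n].copy()
    tans = g.T[:n].copy()
    ss = np.arange(n, dtype=float) * ds
    if outcome == "reached_base" and n >= 2:
        ss[-1] = ss[-2] + float(np.linalg.norm(pts[-1] - pts[-2]))
    traj = Trajectory(s=ss, points=pts, tangents=tans, phi=phis,
                      tube_radius=tube_radius, outcome=outcome,
                      turn_number=turn,
                      metadata={"surface": "papilla",
                                "genotype": shape.descriptors.genotype,
                                "z0": z0, "phi0_deg": phi0_deg,
                                "mu": params.mu, "ds": ds,
                                "contacts": g.contacts,
                                "first_contact_s": first_contact_s,
                                "theta_unwrapped_end":
                                    float(g.theta_rec[n - 1])})
    return traj
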