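"""Analytic papilla and pin-like surfaces of revolution.

The stigmatic papilla is modelled as a surface of revolution around the
z-axis, with z = 0 at the papilla pole and z increasing towards the cell
base (all lengths in micrometres).  The radius profile R(z) is an ellipsoid
cap for the head (0 <= z <= Lhead) joined C2-continuously to a shaft formula
whose two coefficients (a1, a2) are fixed by requiring a radius minimum of
Wneck/2 at z = Lneck.

Pin-like shapes (arbitrary-unit toy surfaces used to study how a neck
constriction bends geodesics) are surfaces of revolution of a clamped cubic
B-spline profile N(u1), scaled by a width W and height H, with the pole at
u1 = 1.

Charts
------
Every surface exposes one or more coordinate charts.  A chart knows the
embedding X(u, v) in R^3 and its first and second derivatives, from which
:func:`metric_and_christoffel` builds the first fundamental form and the
Christoffel symbols of the second kind; the geodesic and tube-growth
integrators consume these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar


class InvalidShapeError(ValueError):
    """Raised when shape descriptors violate the bowling-pin constraints."""


# --------------------------------------------------------------------------
# Shape descriptors and the papilla radius profile
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeDescriptors:
    """The four measurable papilla dimensions (micrometres).

    Lhead : pole-to-head-base distance (head length)
    Lneck : pole-to-neck distance
    Whead : head width (diameter)
    Wneck : neck width (diameter)
    """

    Lhead: float
    Lneck: float
    Whead: float
    Wneck: float
    genotype: str = ""

    def __post_init__(self) -> None:
        for name in ("Lhead", "Lneck", "Whead", "Wneck"):
            if not getattr(self, name) > 0:
                raise InvalidShapeError(f"{name} must be strictly positive")
        if not self.Lneck > self.Lhead:
            raise InvalidShapeError("Lneck must exceed Lhead (neck below head)")
        if not self.Wneck < self.Whead:
            raise InvalidShapeError("Wneck must be smaller than Whead "
                                    "(bowling-pin constriction)")


def compute_shape_coefficients(d: ShapeDescriptors) -> tuple[float, float]:
    """Shaft coefficients (a1, a2) of the papilla radius profile.

    Closed-form solution of the two neck conditions dR/dz(Lneck) = 0 and
    R(Lneck) = Wneck/2 for the shaft branch of :meth:`PapillaShape.radius`.

    Raises
    ------
    InvalidShapeError
        if the descriptors are degenerate (shared denominator vanishes).
    """
    Lh, Ln, Wh, Wn = d.Lhead, d.Lneck, d.Whead, d.Wneck
    if Ln <= Lh:
        raise InvalidShapeError("degenerate descriptors: Lneck <= Lhead")
    denom = 2 * Lh * Ln * Wh + 5 * Lh**2 * Wh - Ln**2 * Wh - 6 * Lh**2 * Wn
    if abs(denom) < 1e-12 * Lh**2 * Wh:
        raise InvalidShapeError("degenerate descriptors: shaft-coefficient "
                                "denominator vanishes")
    num1 = 2 * Lh * Ln * Wh + Lh**2 * Wh - Ln**2 * Wh - 2 * Lh**2 * Wn
    a1 = -(num1**2) / (4 * Lh**2 * (Lh - Ln) ** 2 * denom)
    a2 = 4 * Lh**2 * (Lh - Ln) * (Wh - Wn) / denom
    return a1, a2


@dataclass(frozen=True)
class PapillaShape:
    """Analytic papilla surface of revolution.

    The head (0 <= z <= Lhead) is an ellipsoid of semi-axes Lhead (along z)
    and Whead/2 (radial); the shaft continues it with C2 continuity and has
    a single radius minimum of Wneck/2 at z = Lneck.

    z_base is the observable papilla base (default 60 um) at which turn
    numbers are evaluated; z_c is the activation height of the mechanical
    guidance torque and defaults to Lhead, where the near-spherical cap
    goes over into the cylindrical shaft.
    """

    descriptors: ShapeDescriptors
    z_base: float = 60.0
    z_c: float | None = None
    a1: float = field(init=False)
    a2: float = field(init=False)

    def __post_init__(self) -> None:
        a1, a2 = compute_shape_coefficients(self.descriptors)
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)
        if self.z_c is None:
            object.__setattr__(self, "z_c", self.descriptors.Lhead)
        # the profile must stay positive over the whole observable cell
        zs = np.linspace(1e-3, self.z_base, 400)
        if np.any(self.radius(zs)[0] <= 0):
            raise InvalidShapeError("radius profile non-positive on "
                                    f"(0, {self.z_base}]")

    @property
    def Lhead(self) -> float:
        return self.descriptors.Lhead

    @property
    def Lneck(self) -> float:
        return self.descriptors.Lneck

    def radius(self, z):
        """Radius profile R(z) with analytic first and second derivatives.

        Returns ``(R, dR/dz, d2R/dz2)``; accepts scalars or arrays.
        Values beyond z_base are extrapolations of the shaft formula.
        """
        scalar = np.isscalar(z)
        z = np.asarray(z, dtype=float)
        if np.any(z < 0):
            raise ValueError("z must be non-negative (z=0 is the pole)")
        Lh = self.descriptors.Lhead
        Wh = self.descriptors.Whead
        a1, a2 = self.a1, self.a2
        R = np.empty_like(z)
        R1 = np.empty_like(z)
        R2 = np.empty_like(z)

        head = z <= Lh
        if np.any(head):
            zh = z[head]
            u = (Lh - zh) / Lh
            root = np.sqrt(np.clip(1.0 - u * u, 0.0, None))
            R[head] = 0.5 * Wh * root
            with np.errstate(divide="ignore", invalid="ignore"):
                R1[head] = np.where(root > 0, 0.5 * Wh * u / (Lh * root), np.inf)
                R2[head] = np.where(
                    root > 0,
                    -0.5 * Wh / (Lh**2) * (1.0 / root + u * u / root**3),
                    -np.inf,
                )

        shaft = ~head
        if np.any(shaft):
            zs = z[shaft]
            w = zs - Lh          # > 0 on the shaft
            q = a2 + w           # a2 > 0, so no pole for w >= 0
            R[shaft] = 0.5 * Wh - Wh / (4 * Lh**2) * w * w + a1 * w**3 / q
            R1[shaft] = (-Wh / (2 * Lh**2) * w
                         + a1 * (3 * w * w * q - w**3) / q**2)
            R2[shaft] = (-Wh / (2 * Lh**2)
                         + a1 * (6 * w * q * q - 6 * w * w * q + 2 * w**3)
                         / q**3)
        if scalar:
            return float(R), float(R1), float(R2)
        return R, R1, R2

    def radius_scalar(self, z: float) -> tuple[float, float, float]:
        """Scalar fast path of :meth:`radius` (pure-float, for inner loops)."""
        Lh = self.descriptors.Lhead
        Wh = self.descriptors.Whead
        if z < 0:
            raise ValueError("z must be non-negative (z=0 is the pole)")
        if z <= Lh:
            u = (Lh - z) / Lh
            root = math.sqrt(max(1.0 - u * u, 0.0))
            if root == 0.0:
                return 0.0, math.inf, -math.inf
            return (0.5 * Wh * root,
                    0.5 * Wh * u / (Lh * root),
                    -0.5 * Wh / Lh**2 * (1.0 / root + u * u / root**3))
        a1, a2 = self.a1, self.a2
        w = z - Lh
        q = a2 + w
        return (0.5 * Wh - Wh / (4 * Lh**2) * w * w + a1 * w**3 / q,
                -Wh / (2 * Lh**2) * w + a1 * (3 * w * w * q - w**3) / q**2,
                -Wh / (2 * Lh**2)
                + a1 * (6 * w * q * q - 6 * w * w * q + 2 * w**3) / q**3)

    def surface_point(self, theta, z) -> np.ndarray:
        """Embedded point (R(z) cos, R(z) sin, z); theta wraps mod 2*pi."""
        R = self.radius(z)[0]
        return np.stack([R * np.cos(theta), R * np.sin(theta),
                         np.asarray(z, dtype=float) * np.ones_like(R)], axis=-1)

    # -- charts -----------------------------------------------------------

    def cylindrical_chart(self) -> "PapillaCylindricalChart":
        return PapillaCylindricalChart(self)

    def polecap_chart(self) -> "PoleCapChart":
        return PoleCapChart(self)


# --------------------------------------------------------------------------
# Pin-like surfaces
# --------------------------------------------------------------------------

# Default profile family: clamped cubic B-spline, base at u1=0, pole at
# u1=1.  The central control value (index 3) sets the neck; the remaining
# constants are frozen by calibration against the two published reference
# geodesics (neck diameters 0.43/0.27 a.u. giving 1 and 3.5 turns from the
# standard start; see docs/methods.md).
PIN_DEGREE = 3
PIN_KNOTS = np.array([0, 0, 0, 0, 0.25, 0.5, 0.75, 1, 1, 1, 1], dtype=float)
PIN_BASE_CONTROLS = np.array([0.30, 0.30, 0.24, 0.215, 0.30, 0.3155, 0.0])


class PinShape:
    """Pin-like surface of revolution of a B-spline profile.

    ``S(u1, u2) = (W N(u1) cos u2, W N(u1) sin u2, H u1)`` with u1 in [0, 1]
    (0 = base, 1 = pole) and azimuth u2.  ``control_values`` are the spline
    control ordinates; the neck diameter D is twice the minimum of W*N(u1)
    near mid-height.
    """

    def __init__(self, control_values=PIN_BASE_CONTROLS, W: float = 1.0,
                 H: float = 2.0, degree: int = PIN_DEGREE, knots=PIN_KNOTS):
        control_values = np.asarray(control_values, dtype=float)
        if control_values.size < degree + 1:
            raise ValueError("need at least degree+1 control points")
        if len(knots) != control_values.size + degree + 1:
            raise ValueError("knot vector inconsistent with control points")
        self.control_values = control_values
        self.W = float(W)
        self.H = float(H)
        self._spline = BSpline(np.asarray(knots, float), control_values, degree)
        self._d1 = self._spline.derivative(1)
        self._d2 = self._spline.derivative(2)

    @classmethod
    def with_neck_control(cls, cp3: float, **kw) -> "PinShape":
        """Family member with the central control point set to ``cp3``."""
        c = PIN_BASE_CONTROLS.copy()
        c[3] = cp3
        return cls(control_values=c, **kw)

    @classmethod
    def with_neck_diameter(cls, D: float, **kw) -> "PinShape":
        """Solve for the central control point giving neck diameter ``D``."""
        from scipy.optimize import brentq

        def f(cp3):
            return cls.with_neck_control(cp3, **kw).neck_diameter() - D

        cp3 = brentq(f, 1e-3, 0.6, xtol=1e-12)
        return cls.with_neck_control(cp3, **kw)

    def profile(self, u1):
        """Radius rho = W*N(u1) and its first/second u1-derivatives."""
        u1 = np.clip(u1, 0.0, 1.0)
        return (self.W * self._spline(u1), self.W * self._d1(u1),
                self.W * self._d2(u1))

    def surface_point(self, u1, u2) -> np.ndarray:
        rho = self.W * self._spline(np.clip(u1, 0.0, 1.0))
        return np.stack([rho * np.cos(u2), rho * np.sin(u2),
                         np.asarray(u1, float) * self.H], axis=-1)

    def neck_diameter(self, window: tuple[float, float] = (0.3, 0.7)) -> float:
        """Neck diameter D: twice the minimal radius near mid-height."""
        res = minimize_scalar(lambda u: self.W * float(self._spline(u)),
                              bounds=window, method="bounded",
                              options={"xatol": 1e-10})
        return 2.0 * float(res.fun)

    def chart(self) -> "PinChart":
        return PinChart(self)


# --------------------------------------------------------------------------
# Charts: embeddings and their derivatives
# --------------------------------------------------------------------------

@dataclass
class SurfacePatch:
    """Metric and Christoffel symbols of a chart at one point.

    ``metric`` is the 2x2 first fundamental form, ``christoffel[a, b, c]``
    is Gamma^a_{bc} (symmetric in b, c).
    """

    kind: str
    point: tuple[float, float]
    metric: np.ndarray
    christoffel: np.ndarray


class Chart:
    """Base class: a 2-parameter embedding of (part of) a surface."""

    kind = "abstract"

    def embedding(self, u: float, v: float) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, u: float, v: float) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def hessian(self, u: float, v: float):
        """Second derivatives (X_uu, X_uv, X_vv)."""
        raise NotImplementedError

    def normal(self, u: float, v: float) -> np.ndarray:
        Xu, Xv = self.jacobian(u, v)
        n = np.cross(Xu, Xv)
        return n / np.linalg.norm(n)


class PapillaCylindricalChart(Chart):
    """(theta, z) chart of the papilla; singular only at the pole z=0."""

    kind = "cylindrical"

    def __init__(self, shape: PapillaShape):
        self.shape = shape

    def embedding(self, theta, z):
        R = self.shape.radius(z)[0]
        return np.array([R * math.cos(theta), R * math.sin(theta), z])

    def jacobian(self, theta, z):
        R, R1, _ = self.shape.radius(z)
        ct, st = math.cos(theta), math.sin(theta)
        Xt = np.array([-R * st, R * ct, 0.0])
        Xz = np.array([R1 * ct, R1 * st, 1.0])
        return Xt, Xz

    def hessian(self, theta, z):
        R, R1, R2 = self.shape.radius(z)
        ct, st = math.cos(theta), math.sin(theta)
        Xtt = np.array([-R * ct, -R * st, 0.0])
        Xtz = np.array([-R1 * st, R1 * ct, 0.0])
        Xzz = np.array([R2 * ct, R2 * st, 0.0])
        return Xtt, Xtz, Xzz


class PinChart(Chart):
    """(u1, u2) chart of a pin-like surface (u2 is the azimuth)."""

    kind = "nurbs"

    def __init__(self, pin: PinShape):
        self.pin = pin

    def embedding(self, u1, u2):
        rho = float(self.pin.profile(u1)[0])
        return np.array([rho * math.cos(u2), rho * math.sin(u2),
                         u1 * self.pin.H])

    def jacobian(self, u1, u2):
        rho, d1, _ = (float(x) for x in self.pin.profile(u1))
        c, s = math.cos(u2), math.sin(u2)
        X1 = np.array([d1 * c, d1 * s, self.pin.H])
        X2 = np.array([-rho * s, rho * c, 0.0])
        return X1, X2

    def hessian(self, u1, u2):
        rho, d1, d2 = (float(x) for x in self.pin.profile(u1))
        c, s = math.cos(u2), math.sin(u2)
        X11 = np.array([d2 * c, d2 * s, 0.0])
        X12 = np.array([-d1 * s, d1 * c, 0.0])
        X22 = np.array([-rho * c, -rho * s, 0.0])
        return X11, X12, X22


class PoleCapChart(Chart):
    """Cartesian Monge chart z = f(x, y) over the ellipsoid papilla head.

    Valid for z well below the head equator; used by the integrators when a
    trajectory approaches the pole, where the cylindrical chart degenerates.
    """

    kind = "polecap"

    def __init__(self, shape: PapillaShape):
        self.shape = shape
        self.a = shape.descriptors.Whead / 2.0   # radial semi-axis
        self.c = shape.descriptors.Lhead         # z semi-axis

    # z = c (1 - sqrt(1 - (x^2+y^2)/a^2))
    def _g(self, q):  # g(q) = c (1 - sqrt(1 - q/a^2)), q = x^2 + y^2
        return self.c * (1.0 - math.sqrt(max(1.0 - q / self.a**2, 0.0)))

    def height(self, x, y):
        return self._g(x * x + y * y)

    def _derivs(self, x, y):
        a2, c = self.a**2, self.c
        q = x * x + y * y
        root = math.sqrt(max(1.0 - q / a2, 1e-300))
        g1 = c / (2 * a2 * root)                   # dg/dq
        g2 = c / (4 * a2 * a2 * root**3)           # d2g/dq2
        return g1, g2

    def embedding(self, x, y):
        return np.array([x, y, self.height(x, y)])

    def jacobian(self, x, y):
        g1, _ = self._derivs(x, y)
        return (np.array([1.0, 0.0, 2 * x * g1]),
                np.array([0.0, 1.0, 2 * y * g1]))

    def hessian(self, x, y):
        g1, g2 = self._derivs(x, y)
        Xxx = np.array([0.0, 0.0, 2 * g1 + 4 * x * x * g2])
        Xxy = np.array([0.0, 0.0, 4 * x * y * g2])
        Xyy = np.array([0.0, 0.0, 2 * g1 + 4 * y * y * g2])
        return Xxx, Xxy, Xyy


def metric_and_christoffel(chart: Chart, point) -> SurfacePatch:
    """First fundamental form and Christoffel symbols of the second kind.

    Both are built from scalar products of the first and second derivatives
    of the embedding: g_ab = X_a . X_b and
    Gamma^a_bc = g^{ad} (X_bc . X_d).

    Raises
    ------
    FloatingPointError
        if the metric is (numerically) singular, e.g. exactly at the pole
        of a cylindrical chart -- the signal to switch to the pole-cap chart.
    """
    u, v = float(point[0]), float(point[1])
    Xu, Xv = chart.jacobian(u, v)
    if not (np.all(np.isfinite(Xu)) and np.all(np.isfinite(Xv))):
        raise FloatingPointError(f"degenerate embedding derivatives in "
                                 f"chart {chart.kind!r} at {point}")
    g = np.array([[Xu @ Xu, Xu @ Xv], [Xu @ Xv, Xv @ Xv]])
    det = g[0, 0] * g[1, 1] - g[0, 1] ** 2
    if not det > 1e-14 * max(1.0, g[0, 0] * g[1, 1]):
        raise FloatingPointError(f"singular metric in chart {chart.kind!r} "
                                 f"at {point}")
    second = chart.hessian(u, v)     # (X_uu, X_uv, X_vv)
    basis = (Xu, Xv)
    g_inv = np.linalg.inv(g)
    gamma = np.empty((2, 2, 2))
    idx = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}
    for b in range(2):
        for c in range(2):
            Xbc = second[idx[(b, c)]]
            rhs = np.array([Xbc @ basis[0], Xbc @ basis[1]])
            gamma[:, b, c] = g_inv @ rhs
    return SurfacePatch(kind=chart.kind, point=(u, v), metric=g,
                        christoffel=gamma)
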