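"""Elastic bilayer model of the papilla cell wall and guidance estimation.

The pollen tube (radius r) grows sandwiched between the outer and inner
leaflets of the papilla cell wall, which it bulges outward (amplitude
r_out) and inward (r_in), with r_out + r_in = 2r so the tube is
accommodated.  The cross-section of each bulge is approximated by a
half-ellipse of width 2r.  The papilla itself is a pressurised
quasi-cylinder of radius R_p and turgor p, so the leaflets carry tensile
prestress (hoop twice the axial value), and pushing the inner leaflet
inward does volume work against p.

Energy per unit length of tube, for growth direction d in {lg, ci}:

* cross-ridge stretching of both leaflets: the half-ellipse arc excess
  e(h) strains the fibres crossing the ridge (hoop fibres for a
  longitudinal ridge, axial fibres for a circumferential one), against
  their prestress (linear) and their modulus (quadratic);
* for circumferential growth only, an along-ridge term: the ridge wraps
  around the cylinder, so the displaced material changes circumference by
  +/- (pi/4) h / R_p (outer stretched, inner compressed), again against
  hoop prestress and modulus — this is why circumferential growth deforms
  the wall "in two directions";
* the pressure term p * (pi/2) r r_in.

Minimising over the partition r_out / r_in yields the indentation ratio
alpha = r_out / r_in and the strain energy line density f_d.  The
adimensional alignment strength is mu = (f_ci - f_lg) * ell^2 / chi:
positive mu favours growth along the papilla long axis.

Anisotropy nu = (Y_lg - Y_ci) / (Y_lg + Y_ci) enters through
direction-dependent moduli shared by both leaflets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import ellipe

from .trajectory import TUBE_RADIUS
from .tube_growth import CHI_NOMINAL, GUIDANCE_LENGTH

#: leaflet thickness (um); electron micrographs of the stigmatic wall show
#: a bilayer of order one micrometre, i.e. leaflets of roughly half that
LEAFLET_THICKNESS = 0.6
#: effective papilla turgor pressure (MPa) acting across the inner leaflet
TURGOR_PRESSURE = 0.05
#: papilla radius (um) per genotype geometry
PAPILLA_RADIUS_WT = 7.0
PAPILLA_RADIUS_KTN = 10.0


class InfeasibleAlphaError(RuntimeError):
    """Requested indentation ratio unreachable in the given regime."""


def anisotropy(Y_lg: float, Y_ci: float) -> float:
    """Wall stiffness anisotropy nu = (Y_lg - Y_ci) / (Y_lg + Y_ci).

    nu > 0: stiffer along the papilla axis; antisymmetric under swapping
    the two modul i; bounded in (-1, 1) for positive moduli.
    """
    if Y_lg <= 0 or Y_ci <= 0:
        raise ValueError("Young's moduli must be positive")
    return (Y_lg - Y_ci) / (Y_lg + Y_ci)


def moduli_from_anisotropy(Y_eff: float, nu: float) -> tuple[float, float]:
    """Inverse of :func:`anisotropy` at effective stiffness
    Y_eff = (Y_lg + Y_ci)/2: returns (Y_lg, Y_ci)."""
    if not -1.0 < nu < 1.0:
        raise ValueError("nu must lie in (-1, 1)")
    return Y_eff * (1.0 + nu), Y_eff * (1.0 - nu)


@dataclass(frozen=True)
class WallMechParams:
    """Geometry, elasticity and loading of the bilayer wall model.

    Moduli in MPa, lengths in um, pressure in MPa.  ``nu`` applies the
    same longitudinal/circumferential anisotropy to both leaflets;
    ``Y_out``/``Y_in`` set the (direction-averaged) leaflet stiffnesses.
    """

    Y_out: float = 18.0
    Y_in: float = 18.0
    nu: float = 0.0
    p: float = TURGOR_PRESSURE
    t: float = LEAFLET_THICKNESS
    r: float = TUBE_RADIUS
    R_p: float = PAPILLA_RADIUS_WT
    ell: float = GUIDANCE_LENGTH
    chi: float = CHI_NOMINAL

    def __post_init__(self):
        if self.Y_out <= 0 or self.Y_in <= 0:
            raise ValueError("leaflet moduli must be positive")
        if self.p < 0 or self.t <= 0:
            raise ValueError("pressure must be >= 0 and thickness > 0")
        if not 0 < self.r < self.R_p:
            raise ValueError("need 0 < r < R_p (rho = r/R_p in (0,1))")
        if not -1.0 < self.nu < 1.0:
            raise ValueError("anisotropy nu must lie in (-1, 1)")

    @property
    def Y_eff(self) -> float:
        return 0.5 * (self.Y_out + self.Y_in)

    @property
    def rho(self) -> float:
        return self.r / self.R_p

    def directional(self, leaflet: str) -> tuple[float, float]:
        """(Y_lg, Y_ci) of one leaflet ('out' or 'in')."""
        Y = self.Y_out if leaflet == "out" else self.Y_in
        return Y * (1.0 + self.nu), Y * (1.0 - self.nu)


@dataclass(frozen=True)
class IndentationResult:
    r_out: float
    r_in: float
    alpha: float
    f_lg: float          # strain energy per unit tube length (MPa um^2)
    f_ci: float
    mu: float
    params: WallMechParams = field(repr=False, default=None)


def _half_ellipse_excess(r: float, h: float) -> float:
    """Arc length of a half-ellipse (width 2r, height h) minus the flat
    width 2r."""
    if h <= 0:
        return 0.0
    a, b = max(r, h), min(r, h)
    m = 1.0 - (b / a) ** 2
    return 2.0 * a * float(ellipe(m)) - 2.0 * r


def _energy(params: WallMechParams, direction: str, h_in: float) -> float:
    """Total energy per unit tube length at inner indentation ``h_in``."""
    r, t, p, R_p = params.r, params.t, params.p, params.R_p
    h_out = 2.0 * r - h_in
    N_hoop = 0.5 * p * R_p      # prestress tension per leaflet (MPa um)
    N_ax = 0.25 * p * R_p
    E = p * (math.pi / 2.0) * r * h_in        # volume work against turgor
    for leaflet, h in (("out", h_out), ("in", h_in)):
        Y_lg, Y_ci = params.directional(leaflet)
        e = _half_ellipse_excess(r, h)
        if direction == "lg":                 # ridge along the axis
            N_cross, Y_cross = N_hoop, Y_ci
        elif direction == "ci":               # ridge around the cylinder
            N_cross, Y_cross = N_ax, Y_lg
        else:
            raise ValueError("direction must be 'lg' or 'ci'")
        E += N_cross * e + Y_cross * t * e * e / (4.0 * r)
        if direction == "ci":
            eps_y = (math.pi / 4.0) * h / R_p
            sgn = 1.0 if leaflet == "out" else -1.0
            E += (0.5 * Y_ci * t * eps_y ** 2 + sgn * N_hoop * eps_y) \
                * 2.0 * r
    return E


def _minimize_partition(params: WallMechParams, direction: str
                        ) -> tuple[float, float]:
    """(h_in*, E_min) minimising the energy over the bulge partition."""
    r = params.r
    lo, hi = 1e-4 * r, 2.0 * r * (1.0 - 1e-4 / 2.0)
    res = minimize_scalar(lambda h: _energy(params, direction, h),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:       # pragma: no cover - bounded search converges
        raise RuntimeError(f"indentation minimiser failed: {res.message}")
    return float(res.x), float(res.fun)


def indentation_ratio(params: WallMechParams, direction: str = "lg"
                      ) -> IndentationResult:
    """Solve the bulge partition for one growth direction and report the
    indentation ratio alpha = r_out / r_in together with the strain
    energies of both growth directions and the resulting mu."""
    h_in, f_dir = _minimize_partition(params, direction)
    f = {direction: f_dir}
    other = "ci" if direction == "lg" else "lg"
    f[other] = _minimize_partition(params, other)[1]
    r_out = 2.0 * params.r - h_in
    mu = (f["ci"] - f["lg"]) * params.ell ** 2 / params.chi
    return IndentationResult(r_out=r_out, r_in=h_in, alpha=r_out / h_in,
                             f_lg=f["lg"], f_ci=f["ci"], mu=mu,
                             params=params)


def _alpha_of_contrast(Y_eff: float, delta: float, direction: str,
                       base: WallMechParams) -> float:
    p = replace(base, Y_out=Y_eff + 0.5 * delta, Y_in=Y_eff - 0.5 * delta)
    return indentation_ratio(p, direction).alpha


def solve_rigidity_contrast(alpha_target: float, Y_eff: float,
                            direction: str = "lg", *,
                            base: WallMechParams | None = None
                            ) -> WallMechParams:
    """Find the (Y_in, Y_out) pair at fixed Y_eff = (Y_in + Y_out)/2 whose
    indentation ratio equals ``alpha_target`` (isotropic leaflets).

    alpha decreases monotonically with the contrast Y_out - Y_in (a
    stiffer outer leaflet resists outward bulging); raises
    :class:`InfeasibleAlphaError` when the target is outside the reachable
    range rather than clipping silently.
    """
    if alpha_target <= 0:
        raise ValueError("alpha must be positive")
    base = base or WallMechParams()
    dmax = 2.0 * Y_eff * (1.0 - 1e-6)

    def g(delta):
        return _alpha_of_contrast(Y_eff, delta, direction, base) \
            - alpha_target

    glo, ghi = g(-dmax), g(dmax)
    if not (min(glo, ghi) <= 0.0 <= max(glo, ghi)):
        raise InfeasibleAlphaError(
            f"alpha={alpha_target} unreachable at Y_eff={Y_eff} "
            f"(range [{min(glo, ghi) + alpha_target:.3f}, "
            f"{max(glo, ghi) + alpha_target:.3f}])")
    delta = brentq(g, -dmax, dmax, xtol=1e-10)
    return replace(base, Y_out=Y_eff + 0.5 * delta,
                   Y_in=Y_eff - 0.5 * delta)


def rigidity_contrast_curve(alpha_target: float, Y_eff_values,
                            direction: str = "lg", *,
                            base: WallMechParams | None = None
                            ) -> pd.DataFrame:
    """Tabulate the (Y_in, Y_out) relation reproducing a target alpha.

    Infeasible Y_eff values are flagged (feasible=False, NaN moduli)."""
    rows = []
    for Y_eff in np.atleast_1d(Y_eff_values):
        try:
            prm = solve_rigidity_contrast(alpha_target, float(Y_eff),
                                          direction, base=base)
            rows.append({"Y_eff_MPa": float(Y_eff), "Y_in_MPa": prm.Y_in,
                         "Y_out_MPa": prm.Y_out, "feasible": True})
        except InfeasibleAlphaError:
            rows.append({"Y_eff_MPa": float(Y_eff), "Y_in_MPa": np.nan,
                         "Y_out_MPa": np.nan, "feasible": False})
    return pd.DataFrame(rows)


def alignment_strength(alpha_target: float, Y_eff: float,
                       direction: str = "lg", *,
                       base: WallMechParams | None = None
                       ) -> IndentationResult:
    """Estimate mu for a papilla whose measured indentation ratio is
    ``alpha_target`` at effective wall stiffness ``Y_eff``: solve the
    rigidity contrast, then mu = (f_ci - f_lg) ell^2 / chi."""
    prm = solve_rigidity_contrast(alpha_target, Y_eff, direction, base=base)
    return indentation_ratio(prm, direction)


def anisotropy_sweep(nu_values, Y_eff: float, R_p: float, *,
                     base: WallMechParams | None = None) -> pd.DataFrame:
    """alpha(nu) and mu(nu) curves for equal-stiffness leaflets of common
    anisotropy nu, for both growth directions."""
    base = base or WallMechParams()
    rows = []
    for nu in np.atleast_1d(nu_values):
        prm = replace(base, Y_out=Y_eff, Y_in=Y_eff, nu=float(nu), R_p=R_p)
        res_lg = indentation_ratio(prm, "lg")
        res_ci = indentation_ratio(prm, "ci")
        rows.append({"nu": float(nu), "alpha_long": res_lg.alpha,
                     "alpha_circ": res_ci.alpha, "mu": res_lg.mu,
                     "f_lg": res_lg.f_lg, "f_ci": res_lg.f_ci})
    return pd.DataFrame(rows)
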