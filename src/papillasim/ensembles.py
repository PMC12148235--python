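"""Initial-condition sweeps: turn numbers, phase diagrams, distributions.

A morphological phase diagram records the turn number T of one simulated
tube per cell of a (z0, phi0) grid of pollen landing positions and
emergence angles.  Cumulative turn-number distributions F(T) — the
fraction of papillae whose tube makes at most T revolutions before
reaching the base — weight each z0 row by the papilla surface area of its
landing band (or, alternatively, by its projected area in the x-y plane,
which favours pole attachment); phi0 is weighted uniformly.  Caged
trajectories count as T > 2.5 and only enter the top bin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .geometry import PapillaShape
from .trajectory import Trajectory
from .tube_growth import GuidanceParams, grow_tube

#: turn-number thresholds of the cumulative distribution; the implicit
#: final bin collects everything above (including caged trajectories)
TURN_THRESHOLDS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)
#: numeric stand-in for "more than 2.5 turns" when a mean is needed
CAGED_TURN_SENTINEL = 2.75


def count_turns(traj: Trajectory, z_base: float | None = None) -> float:
    """Turn number: revolutions of the unwrapped azimuth down to the base.

    Trajectories that never reached the base (caged / out of length) get
    ``inf``, i.e. they fall in the T > 2.5 category.
    """
    if len(traj) < 2:
        raise ValueError("trajectory has not started")
    if traj.outcome != "reached_base":
        return math.inf
    if not math.isnan(traj.turn_number):
        return float(traj.turn_number)
    theta = traj.azimuth_unwrapped()
    if z_base is not None:
        z = traj.points[:, 2]
        idx = np.flatnonzero(z >= z_base)
        if idx.size == 0:
            return math.inf
        i = idx[0]
        if i > 0:            # interpolate the crossing
            f = (z_base - z[i - 1]) / max(z[i] - z[i - 1], 1e-30)
            th_end = theta[i - 1] + f * (theta[i] - theta[i - 1])
        else:
            th_end = theta[i]
    else:
        th_end = theta[-1]
    return abs(th_end - theta[0]) / (2.0 * math.pi)


@dataclass
class PhaseDiagram:
    """Turn number T over a (z0, phi0) grid for one shape and one mu."""

    z0: np.ndarray            # nominal landing heights (um)
    phi0: np.ndarray          # emergence angles (deg)
    turns: np.ndarray         # (nz, nphi); inf where caged
    outcomes: np.ndarray      # (nz, nphi) of strings
    shape: PapillaShape | None = None
    mu: float = 0.0
    metadata: dict = field(default_factory=dict)

    def caged_mask(self) -> np.ndarray:
        return ~np.isfinite(self.turns)

    def to_frame(self) -> pd.DataFrame:
        zz, pp = np.meshgrid(self.z0, self.phi0, indexing="ij")
        return pd.DataFrame({"z0_um": zz.ravel(), "phi0_deg": pp.ravel(),
                             "T": self.turns.ravel(),
                             "outcome": self.outcomes.ravel()})

    def to_csv(self, path) -> None:
        meta = dict(self.metadata, mu=self.mu,
                    z0=list(map(float, self.z0)),
                    phi0=list(map(float, self.phi0)))
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta, default=float) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhaseDiagram":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# ").strip()) if \
                first.startswith("#") else {}
            df = pd.read_csv(fh)
        z0 = np.array(meta.pop("z0"))
        phi0 = np.array(meta.pop("phi0"))
        turns = df["T"].to_numpy().reshape(len(z0), len(phi0))
        outcomes = df["outcome"].to_numpy().reshape(len(z0), len(phi0))
        return cls(z0=z0, phi0=phi0, turns=turns, outcomes=outcomes,
                   mu=float(meta.pop("mu", 0.0)), metadata=meta)


def default_grid(shape: PapillaShape, dz0: float = 5.0, dphi0: float = 5.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """The standard sweep grid: z0 from the pole to the landing limit
    2*Lhead in steps of 5 um (0 replaced by 0.5 um to stay clear of the
    pole singularity), phi0 from 0 to 180 deg in steps of 5 deg."""
    z0 = np.arange(0.0, 2.0 * shape.Lhead + 1e-9, dz0)
    z0[z0 == 0.0] = 0.5
    phi0 = np.arange(0.0, 180.0 + 1e-9, dphi0)
    return z0, phi0


def phase_diagram(shape: PapillaShape, mu: float = 0.0, *,
                  z0_grid=None, phi0_grid=None, dz0: float = 5.0,
                  dphi0: float = 5.0, ds: float = 0.1,
                  params: GuidanceParams | None = None,
                  progress=None) -> PhaseDiagram:
    """Run one tube per grid cell.  Fully deterministic; per-cell failures
    become caged outcomes and never abort the sweep."""
    gz, gp = default_grid(shape, dz0, dphi0)
    z0_grid = gz if z0_grid is None else np.asarray(z0_grid, float)
    phi0_grid = gp if phi0_grid is None else np.asarray(phi0_grid, float)
    base = params or GuidanceParams()
    p = GuidanceParams(mu=mu, ell=base.ell, chi=base.chi, z_c=base.z_c)
    turns = np.empty((len(z0_grid), len(phi0_grid)))
    outcomes = np.empty_like(turns, dtype=object)
    for i, z0 in enumerate(z0_grid):
        for j, phi0 in enumerate(phi0_grid):
            try:
                tr = grow_tube(shape, float(z0), float(phi0), p, ds=ds)
                turns[i, j] = tr.turn_number
                outcomes[i, j] = tr.outcome
            except Exception as exc:      # pragma: no cover - defensive
                turns[i, j] = math.inf
                outcomes[i, j] = "caged"
            if progress is not None:
                progress(i, j, turns[i, j], outcomes[i, j])
    return PhaseDiagram(z0=z0_grid, phi0=phi0_grid, turns=turns,
                        outcomes=outcomes, shape=shape, mu=mu,
                        metadata={"genotype": shape.descriptors.genotype,
                                  "ds": ds})


# --------------------------------------------------------------------------
# weighting and cumulative distributions
# --------------------------------------------------------------------------

def _bin_edges(z0: np.ndarray, z_max: float) -> np.ndarray:
    mid = 0.5 * (z0[1:] + z0[:-1])
    return np.concatenate([[0.0], mid, [min(z0[-1] + (z0[-1] - mid[-1]
                                                      if len(mid) else 2.5),
                                            z_max)]]) if len(z0) > 1 else \
        np.array([0.0, z_max])


def landing_weights(shape: PapillaShape, z0: np.ndarray,
                    weighting: str = "area") -> np.ndarray:
    """Per-z0-row landing probabilities.

    'area': the surface-area element dS = 2 pi R sqrt(1 + R'^2) dz
    integrated analytically over each row's z-band up to 2*Lhead (uniform
    attachment probability per unit papilla area).
    'projected': the projected-area element dS = 2 pi R dR over the head
    only (z <= Lhead), favouring attachment at the pole.
    """
    z0 = np.asarray(z0, float)
    if weighting == "area":
        z_max = 2.0 * shape.Lhead
        edges = _bin_edges(z0, z_max)

        def integrand(z):
            R, R1, _ = shape.radius_scalar(z)
            return 2.0 * math.pi * R * math.sqrt(1.0 + R1 * R1)

        w = np.array([quad(integrand, edges[k], edges[k + 1],
                           limit=200)[0] if edges[k + 1] > edges[k] else 0.0
                      for k in range(len(z0))])
    elif weighting == "projected":
        z_max = shape.Lhead
        edges = np.clip(_bin_edges(z0, 2.0 * shape.Lhead), 0.0, z_max)
        R = np.array([shape.radius_scalar(e)[0] for e in edges])
        w = math.pi * (R[1:] ** 2 - R[:-1] ** 2)
        w[w < 0] = 0.0
    else:
        raise ValueError(f"unknown weighting mode {weighting!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate weighting: all weights zero")
    return w / total


@dataclass
class TurnDistribution:
    """Cumulative fraction F(T) at the standard thresholds.

    ``F[k]`` is the fraction of (weighted) papillae with turn number
    <= ``thresholds[k]``; the implicit top bin (> 2.5, including caged)
    closes the distribution at 1.
    """

    thresholds: np.ndarray
    F: np.ndarray
    weighting: str = "area"
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{t:g}" for t in self.thresholds] + [">2.5"]
        return pd.DataFrame({"T_bin": labels,
                             "F": np.concatenate([self.F, [1.0]])})


def cumulative_distribution(pd_: PhaseDiagram, weighting: str = "area"
                            ) -> TurnDistribution:
    """Weighted cumulative turn-number distribution of a phase diagram."""
    shape = pd_.shape
    if shape is None:
        raise ValueError("phase diagram carries no shape; cannot weight")
    wz = landing_weights(shape, pd_.z0, weighting)
    wphi = np.full(len(pd_.phi0), 1.0 / len(pd_.phi0))
    W = np.outer(wz, wphi)
    thresholds = np.array(TURN_THRESHOLDS)
    T = pd_.turns
    F = np.array([W[T <= t].sum() for t in thresholds])
    return TurnDistribution(thresholds=thresholds, F=F, weighting=weighting,
                            metadata={"mu": pd_.mu, **pd_.metadata})


def mean_turn_number(pd_: PhaseDiagram, weighting: str = "area",
                     cap: float = CAGED_TURN_SENTINEL) -> float:
    """Weighted mean turn number with caged cells counted as ``cap``."""
    shape = pd_.shape
    if shape is None:
        raise ValueError("phase diagram carries no shape; cannot weight")
    wz = landing_weights(shape, pd_.z0, weighting)
    wphi = np.full(len(pd_.phi0), 1.0 / len(pd_.phi0))
    W = np.outer(wz, wphi)
    T = np.minimum(pd_.turns, cap)
    return float((W * T).sum())


# --------------------------------------------------------------------------
# comparison with experimental count tables
# --------------------------------------------------------------------------

def experimental_distribution(counts: pd.DataFrame) -> pd.DataFrame:
    """Cumulative fractions and binomial SEM from a turn-count table.

    ``counts`` must have columns ``T_bin`` (labels '0', '0.5', ..., '>2.5')
    and ``count`` (papillae per bin).  SEM of each cumulative fraction p is
    sqrt(p (1-p) / n).
    """
    if counts.empty or counts["count"].sum() == 0:
        raise ValueError("empty experimental count table")
    n = counts["count"].sum()
    F = counts["count"].cumsum() / n
    sem = np.sqrt(F * (1.0 - F) / n)
    return pd.DataFrame({"T_bin": counts["T_bin"], "F_exp": F,
                         "SEM_exp": sem})


def compare_distributions(sim: TurnDistribution, counts: pd.DataFrame
                          ) -> pd.DataFrame:
    """Per-bin difference between a simulated distribution and an
    experimental count table, with the experimental SEM bands."""
    exp = experimental_distribution(counts)
    sim_df = sim.to_frame()
    merged = sim_df.merge(exp, on="T_bin", how="inner")
    if merged.empty:
        raise ValueError("no common T bins between simulation and counts")
    merged["delta"] = merged["F"] - merged["F_exp"]
    return merged
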