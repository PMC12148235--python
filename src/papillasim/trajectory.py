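"""Arc-length-sampled trajectory container shared by all integrators."""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: reference pollen tube radius (um); the excluded-volume capsule radius
TUBE_RADIUS = 2.4


@dataclass
class Trajectory:
    """A 3D path on a surface, sampled at (nearly) uniform arc length.

    Attributes
    ----------
    s : (N,) arc length from the start (um, or a.u. for pin shapes)
    points : (N, 3) embedded positions
    tangents : (N, 3) unit tangent vectors along the path
    phi : (N,) angle between the tangent and the longitudinal surface
        direction, in degrees (0 = towards the base, 180 = towards the
        pole); NaN where undefined (at the pole)
    tube_radius : capsule radius used for self-avoidance
    outcome : 'reached_base' | 'caged' | 'max_length' | 'confined'
    turn_number : revolutions around the axis down to the base
        (``inf`` for trajectories that never reached it)
    """

    s: np.ndarray
    points: np.ndarray
    tangents: np.ndarray
    phi: np.ndarray
    tube_radius: float = TUBE_RADIUS
    outcome: str = "reached_base"
    turn_number: float = np.nan
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.s)

    # -- derived geometric quantities -------------------------------------

    def axis_distance(self) -> np.ndarray:
        """Distance R of each point to the revolution axis."""
        return np.hypot(self.points[:, 0], self.points[:, 1])

    def azimuth_unwrapped(self) -> np.ndarray:
        """Continuous azimuthal angle along the path (no mod-2pi jumps)."""
        theta = np.arctan2(self.points[:, 1], self.points[:, 0])
        return np.unwrap(theta)

    def angular_momentum(self) -> np.ndarray:
        """x v_y - y v_x = R sin(phi) along the path (Clairaut invariant)."""
        x, y = self.points[:, 0], self.points[:, 1]
        vx, vy = self.tangents[:, 0], self.tangents[:, 1]
        return x * vy - y * vx

    def min_self_distance(self, window: int) -> float:
        """Minimum distance of any point to any non-adjacent path segment.

        ``window`` segments on either side of a point are skipped (the tube
        tip may always touch its own neck).  Used to audit the excluded
        volume of self-avoiding trajectories.
        """
        P = self.points
        n = len(P)
        if n < window + 2:
            return np.inf
        A, B = P[:-1], P[1:]
        AB = B - A
        ab2 = np.einsum("ij,ij->i", AB, AB)
        best = np.inf
        for i in range(window + 2, n):
            m = i - window - 1  # segments 0..m-1 are eligible
            ap = P[i] - A[:m]
            t = np.clip(np.einsum("ij,ij->i", ap, AB[:m]) /
                        np.maximum(ab2[:m], 1e-30), 0.0, 1.0)
            closest = A[:m] + t[:, None] * AB[:m]
            d2 = np.einsum("ij,ij->i", (P[i] - closest), (P[i] - closest))
            best = min(best, float(np.sqrt(d2.min())))
        return best

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s": self.s,
            "x": self.points[:, 0], "y": self.points[:, 1],
            "z": self.points[:, 2],
            "tx": self.tangents[:, 0], "ty": self.tangents[:, 1],
            "tz": self.tangents[:, 2],
            "phi_deg": self.phi,
        })

    def to_csv(self, path) -> None:
        """CSV with a ``#``-prefixed JSON metadata header."""
        meta = dict(self.metadata)
        meta.update(outcome=self.outcome, turn_number=self.turn_number,
                    tube_radius=self.tube_radius)
        buf = _io.StringIO()
        buf.write("# " + json.dumps(meta, default=float) + "\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# ").strip()) if \
                first.startswith("#") else {}
            df = pd.read_csv(fh)
        t = cls(
            s=df["s"].to_numpy(),
            points=df[["x", "y", "z"]].to_numpy(),
            tangents=df[["tx", "ty", "tz"]].to_numpy(),
            phi=df["phi_deg"].to_numpy(),
            tube_radius=float(meta.pop("tube_radius", TUBE_RADIUS)),
            outcome=str(meta.pop("outcome", "reached_base")),
            turn_number=float(meta.pop("turn_number", np.nan)),
        )
        t.metadata = meta
        return t
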