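import math

import numpy as np
import pytest

from papillasim import PapillaShape, ShapeDescriptors
from papillasim.ensembles import phase_diagram
from papillasim.geometry import Chart
from papillasim.io import default_shapes


@pytest.fixture(scope="session")
def shapes():
    return default_shapes()


@pytest.fixture(scope="session")
def wt_shape(shapes):
    return shapes["WT"]


@pytest.fixture(scope="session")
def ktn_shape(shapes):
    return shapes["ktn1-5"]


@pytest.fixture(scope="session")
def ktn_pd0(ktn_shape):
    """ktn1-5 zero-guidance phase diagram on the standard grid."""
    return phase_diagram(ktn_shape, mu=0.0)


@pytest.fixture(scope="session")
def wt_pd_by_mu(wt_shape):
    """WT phase diagrams across guidance strengths (coarsened phi0 grid
    keeps the sweep cheap; the grid is identical for all mu)."""
    return {mu: phase_diagram(wt_shape, mu=mu, dphi0=15.0)
            for mu in (0.0, 0.01, 0.025, 0.05, 0.1)}


class CylinderChart(Chart):
    """(theta, z) chart of a straight cylinder of radius R0 (test oracle)."""

    kind = "cylinder"

    def __init__(self, R0):
        self.R0 = R0

    def embedding(self, theta, z):
        return np.array([self.R0 * math.cos(theta),
                         self.R0 * math.sin(theta), z])

    def jacobian(self, theta, z):
        return (np.array([-self.R0 * math.sin(theta),
                          self.R0 * math.cos(theta), 0.0]),
                np.array([0.0, 0.0, 1.0]))

    def hessian(self, theta, z):
        return (np.array([-self.R0 * math.cos(theta),
                          -self.R0 * math.sin(theta), 0.0]),
                np.zeros(3), np.zeros(3))


class SphereChart(Chart):
    """(u, v) = (polar, azimuth) chart of the unit sphere (test oracle)."""

    kind = "sphere"

    def embedding(self, u, v):
        return np.array([math.sin(u) * math.cos(v),
                         math.sin(u) * math.sin(v), math.cos(u)])

    def jacobian(self, u, v):
        return (np.array([math.cos(u) * math.cos(v),
                          math.cos(u) * math.sin(v), -math.sin(u)]),
                np.array([-math.sin(u) * math.sin(v),
                          math.sin(u) * math.cos(v), 0.0]))

    def hessian(self, u, v):
        Xuu = -self.embedding(u, v)
        Xuv = np.array([-math.cos(u) * math.sin(v),
                        math.cos(u) * math.cos(v), 0.0])
        Xvv = np.array([-math.sin(u) * math.cos(v),
                        -math.sin(u) * math.sin(v), 0.0])
        return Xuu, Xuv, Xvv


@pytest.fixture
def cylinder_chart():
    return CylinderChart


@pytest.fixture
def sphere_chart():
    return SphereChart


def make_shape(Lh=8.25, Ln=40.0, Wh=16.5, Wn=14.4, genotype="test"):
    return PapillaShape(ShapeDescriptors(Lhead=Lh, Lneck=Ln, Whead=Wh,
                                         Wneck=Wn, genotype=genotype))
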