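import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from papillasim import (InvalidShapeError, PapillaShape, PinShape,
                        ShapeDescriptors, compute_shape_coefficients,
                        metric_and_christoffel)

# descriptor ranges spanning the measured WT/ktn1-5 morphologies
valid_descriptors = st.builds(
    lambda Lh, dLn, Wh, fWn: ShapeDescriptors(
        Lhead=Lh, Lneck=Lh + dLn, Whead=Wh, Wneck=fWn * Wh),
    Lh=st.floats(5.0, 20.0), dLn=st.floats(8.0, 40.0),
    Wh=st.floats(10.0, 30.0), fWn=st.floats(0.55, 0.95),
)


class TestShapeDescriptors:
    @pytest.mark.parametrize("kw", [
        dict(Lhead=-1, Lneck=40, Whead=16, Wneck=14),
        dict(Lhead=8, Lneck=8, Whead=16, Wneck=14),     # neck not below head
        dict(Lhead=8, Lneck=40, Whead=14, Wneck=16),    # no constriction
        dict(Lhead=8, Lneck=40, Whead=16, Wneck=0.0),
    ])
    def test_invalid_descriptors_rejected(self, kw):
        with pytest.raises(InvalidShapeError):
            ShapeDescriptors(**kw)


class TestShapeCoefficients:
    def test_against_numeric_root_finding(self):
        """(a1, a2) agree with an independent numeric solve of the two
        neck conditions (zero slope and half neck width at Lneck)."""
        d = ShapeDescriptors(Lhead=8.25, Lneck=40.0, Whead=16.50,
                             Wneck=14.40)
        Lh, Wh = d.Lhead, d.Whead
        w = d.Lneck - Lh

        def conditions(x):
            a1, a2 = x
            R = 0.5 * Wh - Wh / (4 * Lh**2) * w**2 + a1 * w**3 / (a2 + w)
            dR = (-Wh / (2 * Lh**2) * w
                  + a1 * (3 * w**2 * (a2 + w) - w**3) / (a2 + w) ** 2)
            return [R - 0.5 * d.Wneck, dR]

        oracle = fsolve(conditions, x0=[0.05, 1.0], full_output=False)
        a1, a2 = compute_shape_coefficients(d)
        assert a1 == pytest.approx(oracle[0], rel=1e-8)
        assert a2 == pytest.approx(oracle[1], rel=1e-8)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(valid_descriptors)
    def test_neck_conditions(self, d):
        """The shaft formula hits Wneck/2 with zero slope at the neck."""
        shape = PapillaShape.__new__(PapillaShape)  # bypass positivity check
        object.__setattr__(shape, "descriptors", d)
        a1, a2 = compute_shape_coefficients(d)
        object.__setattr__(shape, "a1", a1)
        object.__setattr__(shape, "a2", a2)
        R, R1, _ = shape.radius(d.Lneck)
        assert R == pytest.approx(d.Wneck / 2, rel=1e-9)
        assert abs(R1) < 1e-9 * d.Wneck

    @pytest.mark.parametrize("kw", [
        # Lneck <= Lhead (constructed past the dataclass validation)
        dict(Lhead=10.0, Lneck=10.0, Whead=16.0, Wneck=14.0),
        # shared denominator of the closed-form coefficients vanishes
        dict(Lhead=10.0, Lneck=20.0, Whead=16.0, Wneck=16.0 * 500 / 600),
    ])
    def test_degenerate_descriptors_raise(self, kw):
        d = ShapeDescriptors.__new__(ShapeDescriptors)
        for k, v in kw.items():
            object.__setattr__(d, k, v)
        object.__setattr__(d, "genotype", "")
        with pytest.raises(InvalidShapeError):
            compute_shape_coefficients(d)


class TestPapillaRadius:
    def test_pole_head_and_neck_values(self, wt_shape):
        d = wt_shape.descriptors
        assert wt_shape.radius(0.0)[0] == pytest.approx(0.0, abs=1e-12)
        assert wt_shape.radius(d.Lhead)[0] == pytest.approx(d.Whead / 2)
        assert wt_shape.radius(d.Lneck)[0] == pytest.approx(d.Wneck / 2)

    def test_negative_z_rejected(self, wt_shape):
        with pytest.raises(ValueError):
            wt_shape.radius(-0.1)
        with pytest.raises(ValueError):
            wt_shape.radius_scalar(-0.1)

    def test_c2_continuity_at_head_base(self, wt_shape, ktn_shape):
        eps = 1e-6
        for shape in (wt_shape, ktn_shape):
            Lh = shape.Lhead
            lo = shape.radius(Lh - eps)
            hi = shape.radius(Lh + eps)
            assert lo[0] == pytest.approx(hi[0], abs=1e-9)
            assert lo[1] == pytest.approx(hi[1], abs=1e-5)
            assert lo[2] == pytest.approx(hi[2], abs=1e-4)

    def test_scalar_matches_array_path(self, ktn_shape):
        zs = np.linspace(0.5, 60.0, 37)
        R, R1, R2 = ktn_shape.radius(zs)
        for k, z in enumerate(zs):
            r, r1, r2 = ktn_shape.radius_scalar(float(z))
            assert (r, r1, r2) == pytest.approx((R[k], R1[k], R2[k]),
                                                rel=1e-12)

    def test_single_valley_at_neck(self, wt_shape, ktn_shape):
        """R is positive with a unique interior minimum at Lneck."""
        for shape in (wt_shape, ktn_shape):
            zs = np.linspace(shape.Lhead, shape.z_base, 2000)
            R = shape.radius(zs)[0]
            assert np.all(R > 0)
            z_min = zs[np.argmin(R)]
            assert z_min == pytest.approx(shape.Lneck, abs=0.1)
            sign_changes = np.sum(np.diff(np.sign(np.diff(R))) != 0)
            assert sign_changes == 1


class TestSurfacePoints:
    def test_head_base_point(self, wt_shape):
        p = wt_shape.surface_point(0.0, wt_shape.Lhead)
        assert p == pytest.approx([wt_shape.descriptors.Whead / 2, 0.0,
                                   wt_shape.Lhead])

    def test_periodicity_and_rotation(self, wt_shape):
        p1 = wt_shape.surface_point(0.7, 20.0)
        p2 = wt_shape.surface_point(0.7 + 2 * math.pi, 20.0)
        assert p1 == pytest.approx(p2, abs=1e-12)
        # rotating theta by delta rotates the point about the z-axis
        delta = 0.31
        p3 = wt_shape.surface_point(0.7 + delta, 20.0)
        c, s = math.cos(delta), math.sin(delta)
        rot = np.array([c * p1[0] - s * p1[1], s * p1[0] + c * p1[1], p1[2]])
        assert p3 == pytest.approx(rot, abs=1e-12)

    def test_axis_distance_equals_radius(self, ktn_shape):
        z = 33.0
        p = ktn_shape.surface_point(2.1, z)
        assert math.hypot(p[0], p[1]) == pytest.approx(
            ktn_shape.radius(z)[0])


class TestPinShape:
    def test_revolution_symmetry_and_scaling(self):
        pin = PinShape()
        p = pin.surface_point(0.4, 0.0)
        assert p[1] == pytest.approx(0.0, abs=1e-12)
        pin2 = PinShape(W=2.0)
        q = pin2.surface_point(0.4, 0.3)
        q1 = pin.surface_point(0.4, 0.3)
        assert q[0] == pytest.approx(2 * q1[0])
        assert q[1] == pytest.approx(2 * q1[1])
        assert q[2] == pytest.approx(q1[2])     # z unchanged by W

    @pytest.mark.parametrize("D", [0.43, 0.27])
    def test_neck_diameter_solved_from_central_control(self, D):
        pin = PinShape.with_neck_diameter(D)
        assert pin.neck_diameter() == pytest.approx(D, abs=1e-6)

    def test_too_few_control_points(self):
        with pytest.raises(ValueError):
            PinShape(control_values=[0.3, 0.2], knots=[0, 0, 0, 1, 1, 1])


class TestMetricAndChristoffel:
    def test_cylinder_symbols_vanish(self, cylinder_chart):
        patch = metric_and_christoffel(cylinder_chart(3.0), (0.4, 7.0))
        assert patch.christoffel == pytest.approx(np.zeros((2, 2, 2)),
                                                  abs=1e-12)
        assert patch.metric == pytest.approx(np.diag([9.0, 1.0]))

    def test_sphere_symbols_match_closed_form(self, sphere_chart):
        u, v = 0.8, 1.3
        patch = metric_and_christoffel(sphere_chart(), (u, v))
        expected = np.zeros((2, 2, 2))
        expected[0, 1, 1] = -math.sin(u) * math.cos(u)
        expected[1, 0, 1] = expected[1, 1, 0] = math.cos(u) / math.sin(u)
        assert patch.christoffel == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("point", [(0.3, 12.0), (2.0, 25.0), (4.5, 45.0)])
    def test_symmetry_and_finite_difference(self, wt_shape, point):
        chart = wt_shape.cylindrical_chart()
        patch = metric_and_christoffel(chart, point)
        assert patch.christoffel[:, 0, 1] == pytest.approx(
            patch.christoffel[:, 1, 0], abs=1e-12)
        # numeric check of Gamma^a_bc = g^{ad} (X_bc . X_d) with
        # finite-difference second derivatives of the embedding
        h = 1e-4
        u, v = point

        def emb(uu, vv):
            return chart.embedding(uu, vv)

        Xu = (emb(u + h, v) - emb(u - h, v)) / (2 * h)
        Xv = (emb(u, v + h) - emb(u, v - h)) / (2 * h)
        Xuu = (emb(u + h, v) - 2 * emb(u, v) + emb(u - h, v)) / h**2
        Xvv = (emb(u, v + h) - 2 * emb(u, v) + emb(u, v - h)) / h**2
        Xuv = (emb(u + h, v + h) - emb(u + h, v - h)
               - emb(u - h, v + h) + emb(u - h, v - h)) / (4 * h**2)
        g = np.array([[Xu @ Xu, Xu @ Xv], [Xu @ Xv, Xv @ Xv]])
        ginv = np.linalg.inv(g)
        second = {(0, 0): Xuu, (0, 1): Xuv, (1, 0): Xuv, (1, 1): Xvv}
        for b in range(2):
            for c in range(2):
                rhs = np.array([second[(b, c)] @ Xu, second[(b, c)] @ Xv])
                gamma_fd = ginv @ rhs
                assert patch.christoffel[:, b, c] == pytest.approx(
                    gamma_fd, rel=1e-5, abs=1e-6)

    def test_singular_at_pole(self, wt_shape):
        with pytest.raises(FloatingPointError):
            metric_and_christoffel(wt_shape.cylindrical_chart(), (0.0, 0.0))
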