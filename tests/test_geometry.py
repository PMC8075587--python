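"""Framed-curve geometry: frame integration, strain recovery, torsion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lassobeat import (
    ArcGrid,
    BendingTwistField,
    bending_twist_from_frame,
    curvature_torsion_from_bending,
    curvature_torsion_from_centerline,
    integrate_frame,
    mt_centerlines,
    project_outline,
    shear_from_bending,
    torsion_dipole_curve,
)
from lassobeat.fixtures import circle_points, helix_points

from conftest import smooth_bending


class TestIntegrateFrame:
    def test_zero_strains_give_straight_segment(self):
        grid = ArcGrid(64, 2.0)
        c = integrate_frame(BendingTwistField.constant(grid, 0, 0, 0))
        assert np.allclose(c.r[:, 2], grid.s)
        assert np.allclose(c.r[:, :2], 0.0)
        assert np.allclose(c.d1, [1, 0, 0]) and np.allclose(c.d3, [0, 0, 1])

    def test_semicircular_arc(self):
        # constant bending K over length pi/K closes half a circle of
        # radius 1/K: endpoint sits a diameter away from the base
        K = 2.0
        grid = ArcGrid(1001, np.pi / K)
        c = integrate_frame(BendingTwistField.constant(grid, 0.0, K, 0.0))
        dist = np.linalg.norm(c.r[-1] - c.r[0])
        assert abs(dist - 2.0 / K) < 1e-6 * (2.0 / K)
        # arc stays in the d1-d3 plane of the base frame
        assert np.abs(c.r[:, 1]).max() < 1e-12

    def test_helix_matches_closed_form(self):
        # U = (0, k, t) constant traces a circular helix whose curvature and
        # torsion equal k and t
        k, t = 3.0, 1.2
        grid = ArcGrid(800, 2.0)
        U = BendingTwistField.constant(grid, 0.0, k, t)
        ct = curvature_torsion_from_bending(U)
        assert np.allclose(ct.kappa, k)
        assert np.allclose(ct.tau[ct.valid_mask], t, atol=1e-9)
        # cross-check on the integrated centerline
        ct2 = curvature_torsion_from_centerline(integrate_frame(U).r)
        m = ct2.valid_mask
        assert np.abs(ct2.kappa[m] - k).max() < 0.01 * k
        assert np.abs(ct2.tau[m] - t).max() < 0.01 * max(t, k)

    def test_orthonormality_preserved(self):
        rng = np.random.default_rng(11)
        for n in (64, 301):
            U = smooth_bending(ArcGrid(n, 1.0), rng, amp=5.0, twist=True)
            assert integrate_frame(U).frame_defect() < 1e-10

    def test_rejects_bad_base_frame(self):
        grid = ArcGrid(16, 1.0)
        U = BendingTwistField.constant(grid, 0, 1, 0)
        bad = (np.array([1.0, 0, 0]), np.array([1.0, 0, 0]), np.array([0, 0, 1.0]))
        with pytest.raises(ValueError):
            integrate_frame(U, base_frame=bad)


class TestRoundTrip:
    def test_constant_frame_gives_zero_strains(self):
        grid = ArcGrid(32, 1.0)
        c = integrate_frame(BendingTwistField.constant(grid, 0, 0, 0))
        U = bending_twist_from_frame(c)
        assert np.abs(U.as_matrix()).max() < 1e-12

    def test_circle_frame_strains(self):
        R = 0.5
        grid = ArcGrid(256, 2.0)
        c = integrate_frame(BendingTwistField.constant(grid, 0.0, 1 / R, 0.0))
        U = bending_twist_from_frame(c)
        assert np.abs(U.U2 - 1 / R).max() < 20 * grid.h**2
        assert np.abs(U.U1).max() < 1e-10 and np.abs(U.U3).max() < 1e-10

    def test_second_order_convergence(self):
        errs = []
        for n in (101, 201, 401):
            rng = np.random.default_rng(42)
            U = smooth_bending(ArcGrid(n, 1.0), rng, twist=True)
            U2 = bending_twist_from_frame(integrate_frame(U))
            errs.append(np.abs(U2.as_matrix() - U.as_matrix()).max())
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0


class TestShearFromBending:
    def test_circular_arc_shear_grows_linearly(self):
        # gamma1(s) = K s for an arc with U2 = K; the base carries no shear
        K = 1.7
        grid = ArcGrid(128, 1.0)
        g = shear_from_bending(BendingTwistField.constant(grid, 0.0, K, 0.0))
        assert g.gamma1[0] == 0.0 and g.gamma2[0] == 0.0
        assert np.allclose(g.gamma1, K * grid.s)
        assert np.allclose(g.gamma2, 0.0)

    def test_sine_antiderivative(self):
        grid = ArcGrid(512, 1.0)
        s = grid.s
        U = BendingTwistField(grid, np.zeros_like(s), np.sin(2 * np.pi * s),
                              np.zeros_like(s))
        g = shear_from_bending(U)
        exact = (1 - np.cos(2 * np.pi * s)) / (2 * np.pi)
        assert np.abs(g.gamma1 - exact).max() < 1e-5

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, a, b):
        grid = ArcGrid(64, 1.0)
        rng = np.random.default_rng(0)
        U1 = smooth_bending(grid, rng)
        U2 = smooth_bending(grid, rng)
        combo = BendingTwistField(
            grid, a * U1.U1 + b * U2.U1, a * U1.U2 + b * U2.U2,
            a * U1.U3 + b * U2.U3,
        )
        g = shear_from_bending(combo)
        ga, gb = shear_from_bending(U1), shear_from_bending(U2)
        assert np.allclose(g.gamma1, a * ga.gamma1 + b * gb.gamma1, atol=1e-9)
        assert np.allclose(g.gamma2, a * ga.gamma2 + b * gb.gamma2, atol=1e-9)


class TestCurvatureTorsionFromBending:
    def test_rotating_bending_vector(self):
        # U = kappa0 (cos ws, sin ws): constant curvature, torsion w
        grid = ArcGrid(400, 1.0)
        k0, w = 2.5, 7.0
        U = BendingTwistField(grid, k0 * np.cos(w * grid.s),
                              k0 * np.sin(w * grid.s), np.zeros(grid.n_nodes))
        ct = curvature_torsion_from_bending(U)
        assert np.allclose(ct.kappa, k0)
        assert np.abs(ct.tau[ct.valid_mask] - w).max() < 1e-3 * w

    def test_zero_field_has_empty_mask(self):
        grid = ArcGrid(32, 1.0)
        ct = curvature_torsion_from_bending(BendingTwistField.constant(grid, 0, 0, 0))
        assert not ct.valid_mask.any()
        assert ct.max_abs_tau() == 0.0

    def test_planar_inflection_stays_planar(self):
        # bending vector crossing zero along a line: torsion must remain 0
        grid = ArcGrid(256, 1.0)
        U2 = 1.5 * np.sin(2 * np.pi * grid.s)  # sign changes
        U = BendingTwistField(grid, np.zeros_like(U2), U2, np.zeros_like(U2))
        ct = curvature_torsion_from_bending(U)
        assert ct.max_abs_tau() < 1e-12


class TestCurvatureTorsionFromCenterline:
    def test_planar_circle(self):
        ct = curvature_torsion_from_centerline(circle_points(2.0, 200))
        m = ct.valid_mask
        assert np.abs(ct.tau[m]).max() < 1e-8
        assert np.abs(ct.kappa[m] - 0.5).max() < 0.005 * 0.5

    @given(a=st.floats(0.5, 2.0), b=st.floats(0.1, 1.0))
    @settings(max_examples=10, deadline=None)
    def test_helix_closed_form(self, a, b):
        ct = curvature_torsion_from_centerline(helix_points(a, b, 200))
        m = ct.valid_mask
        kap, tau = a / (a**2 + b**2), b / (a**2 + b**2)
        assert np.abs(ct.kappa[m] - kap).max() < 0.01 * kap
        assert np.abs(ct.tau[m] - tau).max() < 0.01 * max(tau, kap)

    def test_right_handed_helix_has_positive_torsion(self):
        ct = curvature_torsion_from_centerline(helix_points(1.0, 0.3, 200))
        assert np.all(ct.tau[ct.valid_mask] > 0)
        left = helix_points(1.0, 0.3, 200) * np.array([1.0, 1.0, -1.0])
        ct2 = curvature_torsion_from_centerline(left)
        assert np.all(ct2.tau[ct2.valid_mask] < 0)

    def test_agrees_with_strain_route(self):
        # internal cross-oracle on an integrated random twistless shape
        rng = np.random.default_rng(7)
        grid = ArcGrid(801, 1.0)
        U = smooth_bending(grid, rng, amp=3.0, offset=4.0)
        ctb = curvature_torsion_from_bending(U)
        ctc = curvature_torsion_from_centerline(integrate_frame(U).r)
        m = ctb.valid_mask & ctc.valid_mask & (ctb.kappa >= 10 * 1e-3)
        scale = np.abs(ctb.tau[m]).max()
        assert np.abs(ctb.tau[m] - ctc.tau[m]).max() < 0.02 * scale
        assert np.abs(ctb.kappa[m] - ctc.kappa[m]).max() < 0.02 * ctb.kappa[m].max()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            curvature_torsion_from_centerline(np.zeros((4, 3)))
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                       dtype=float)
        with pytest.raises(ValueError):
            curvature_torsion_from_centerline(pts)


class TestMtCenterlines:
    def test_straight_axoneme_gives_parallel_lines(self):
        grid = ArcGrid(64, 1.0)
        U = BendingTwistField.constant(grid, 0, 0, 0)
        g = shear_from_bending(U)
        mts = mt_centerlines(U, g, rho_a=0.01)
        assert len(mts) == 9
        for rj in mts:
            radial = np.linalg.norm(rj[:, :2], axis=1)
            assert np.allclose(radial, 0.01)
            assert np.allclose(rj[:, 2], grid.s)

    def test_mt2_sits_on_d1_axis(self):
        # doublet 2 lies at angle 0: r2 = ra + rho (d1 + gamma1 d3)
        grid = ArcGrid(256, 1.0)
        K, rho = 1.3, 0.01
        U = BendingTwistField.constant(grid, 0.0, K, 0.0)
        g = shear_from_bending(U)
        c = integrate_frame(U)
        r2 = mt_centerlines(U, g, rho)[1]
        expected = c.r + rho * (c.d1 + g.gamma1[:, None] * c.d3)
        assert np.abs(r2 - expected).max() < 1e-14

    def test_energy_aggregation_ratio_tends_to_nine(self):
        # the nine doublets behave as one rod of ninefold bending modulus
        grid = ArcGrid(1001, 1.0)
        s = grid.s
        U = BendingTwistField(grid, np.full_like(s, 0.3),
                              2 * np.pi * (1 + 0.5 * np.sin(2 * np.pi * s)),
                              np.zeros_like(s))
        g = shear_from_bending(U)
        ratios = []
        for rho in (4e-3, 1e-3):
            total = 0.0
            for rj in mt_centerlines(U, g, rho):
                ct = curvature_torsion_from_centerline(rj)
                total += 0.5 * np.trapezoid(ct.kappa**2, ct.grid.s)
            ratios.append(total / (0.5 * np.trapezoid(U.U1**2 + U.U2**2, s)))
        assert abs(ratios[-1] - 9.0) < 0.09  # 1% at rho_a/L = 1e-3
        assert abs(ratios[1] - 9.0) < abs(ratios[0] - 9.0)  # error shrinks with rho


class TestTorsionDipole:
    def test_impulse_pair_and_zero_net(self):
        grid = ArcGrid(601, 3.0)
        c = torsion_dipole_curve(np.pi / 2, (1.0, 1.0, 1.0), grid)
        ct = curvature_torsion_from_bending(bending_twist_from_frame(c))
        s, tau = grid.s, ct.tau
        pos = np.trapezoid(np.where(tau > 0, tau, 0), s)
        neg = np.trapezoid(np.where(tau < 0, tau, 0), s)
        assert abs(pos - np.pi / 2) < 0.03 * np.pi / 2
        assert abs(neg + np.pi / 2) < 0.03 * np.pi / 2
        assert abs(np.trapezoid(tau, s)) < 1e-10

    def test_zero_rotation_is_planar(self):
        c = torsion_dipole_curve(0.0)
        ct = curvature_torsion_from_bending(bending_twist_from_frame(c))
        assert ct.max_abs_tau() < 1e-10
        assert np.abs(c.r[:, np.argmin(np.abs(c.r).max(axis=0))]).max() < 1e-9

    def test_generic_views_show_looping_outline(self):
        c = torsion_dipole_curve()
        rng = np.random.default_rng(0)
        hits = 0
        for v in rng.normal(size=(20, 3)):
            _, flag = project_outline(c, v / np.linalg.norm(v))
            hits += flag
        assert hits >= 10  # loops for a dense set of view directions


class TestProjectOutline:
    def test_straight_line_never_loops(self):
        grid = ArcGrid(64, 1.0)
        c = integrate_frame(BendingTwistField.constant(grid, 0, 0, 0))
        _, flag = project_outline(c, np.array([1.0, 0.0, 0.0]))
        assert not flag

    def test_planar_simple_curve_face_on(self):
        grid = ArcGrid(101, 1.0)
        c = integrate_frame(BendingTwistField.constant(grid, 0.0, 2.0, 0.0))
        _, flag = project_outline(c, np.array([0.0, 1.0, 0.0]))
        assert not flag

    def test_requires_unit_view(self):
        grid = ArcGrid(16, 1.0)
        c = integrate_frame(BendingTwistField.constant(grid, 0, 0, 0))
        with pytest.raises(ValueError):
            project_outline(c, np.array([1.0, 1.0, 0.0]))
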