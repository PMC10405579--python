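"""Structure factors: oriented, Debye-averaged, extracted from intensity,
and Fourier-transformed from g(r)."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

import oriscat as osc
from oriscat.errors import ValidationError


class TestOriented:
    def test_single_point_gives_unity_anywhere(self):
        pts = osc.PointSet(np.array([[1.2, -0.7, 4.0]]))
        qv = np.array([[0, 0, 0], [2, 1, -1.0]])
        np.testing.assert_allclose(osc.structure_factor_oriented(pts, qv), 1.0)

    def test_forward_direction_gives_n(self):
        pts = osc.cubic_crystal(2.0, (3, 3, 3))
        got = osc.structure_factor_oriented(pts, np.zeros((1, 3)))
        assert got[0] == pytest.approx(27.0)

    def test_two_points_interfere_destructively_at_pi_over_d(self):
        d = 1.7
        pts = osc.PointSet(np.array([[0, 0, 0], [0, 0, d]]))
        got = osc.structure_factor_oriented(pts, np.array([[0, 0, np.pi / d]]))
        assert got[0] == pytest.approx(0.0, abs=1e-12)


class TestDebye:
    def test_single_point_model_is_flat_unity(self):
        pts = osc.PointSet(np.array([[3.0, 2.0, 1.0]]))
        sq = osc.s_q_from_model(pts, np.linspace(0, 5, 11))
        np.testing.assert_allclose(sq.S, 1.0)

    def test_forward_limit_equals_n(self):
        pts = osc.cubic_crystal(2.0, (2, 3, 4))
        sq = osc.s_q_from_model(pts, np.array([0.0, 0.5]))
        assert sq.S[0] == pytest.approx(24.0)

    def test_debye_equals_orientation_average_of_oriented_sum(self):
        # 3 collinear points at 2 nm spacing, q = 1 nm^-1; MC oracle over
        # uniform random q directions
        pts = osc.PointSet(np.array([[0, 0, -2.0], [0, 0, 0], [0, 0, 2.0]]))
        q = 1.0
        rng = np.random.default_rng(7)
        n = 100_000
        u = 2 * rng.random(n) - 1
        phi = 2 * np.pi * rng.random(n)
        stheta = np.sqrt(1 - u ** 2)
        qv = q * np.stack([stheta * np.cos(phi), stheta * np.sin(phi), u], axis=1)
        vals = osc.structure_factor_oriented(pts, qv)
        mc, sem = vals.mean(), vals.std() / np.sqrt(n)
        debye = osc.s_q_from_model(pts, np.array([q])).S[0]
        assert abs(debye - mc) < 4 * sem

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = osc.PointSet(rng.random((12, 3)) * 4.0)
        rot = Rotation.random(random_state=seed).as_matrix()
        moved = osc.PointSet(pts.positions @ rot.T + rng.normal(size=3))
        q = np.linspace(0.1, 6.0, 25)
        np.testing.assert_allclose(osc.s_q_from_model(pts, q).S,
                                   osc.s_q_from_model(moved, q).S,
                                   rtol=1e-9, atol=1e-9)

    def test_histogrammed_sum_matches_direct_sum(self):
        # 13^3 = 2197 points triggers the histogram path; oracle is the
        # explicit pair sum
        pts = osc.cubic_crystal(1.2, (13, 13, 13))
        q = np.array([0.8, 2.0, 4.5])
        got = osc.s_q_from_model(pts, q).S
        d = pdist(pts.positions)
        ref = 1.0 + 2.0 / pts.n * np.array(
            [np.sinc(qi * d / np.pi).sum() for qi in q])
        np.testing.assert_allclose(got, ref, rtol=2e-4)

    def test_thermal_averaging_damps_bragg_peak(self):
        pts = osc.cubic_crystal(3.5, (5, 5, 5))
        q_bragg = np.array([2 * np.pi / 3.5])
        cold = osc.s_q_from_model(pts, q_bragg).S[0]
        fluct = osc.FluctuationSpec("gaussian", sigma_u=0.15, seed=21)
        warm = osc.s_q_from_model(pts, q_bragg, n_thermal=8, fluct=fluct).S[0]
        assert warm < cold

    def test_thermal_averaging_requires_fluctuation_spec(self):
        pts = osc.cubic_crystal(2.0, (2, 2, 2))
        with pytest.raises(ValidationError):
            osc.s_q_from_model(pts, np.array([1.0]), n_thermal=4)


class TestFromIntensity:
    def test_ideal_gas_inversion_returns_unity(self):
        q = np.linspace(0.1, 4.0, 50)
        ff = osc.solution_form_factor(osc.SubunitModel.sphere(1.0), q)
        intensity = osc.ScatteringCurve(q, 7 * ff.I)
        sq = osc.s_q_from_intensity(intensity, ff, 7)
        np.testing.assert_allclose(sq.S, 1.0, rtol=1e-12)

    def test_sphere_decorated_crystal_recovers_model_structure_factor(
            self, crystal10, sphere_crystal_curve):
        q = sphere_crystal_curve.q
        ff = osc.solution_form_factor(osc.SubunitModel.sphere(1.5), q)
        rec = osc.s_q_from_intensity(sphere_crystal_curve, ff, crystal10.n)
        ref = osc.s_q_from_model(crystal10, q)
        np.testing.assert_allclose(rec.S, ref.S, rtol=1e-8)

    def test_cylinder_assumption_breaks_down_by_q_of_three(self):
        # intensity of a crystal of parallel cylinders couples the form factor
        # and the lattice sum, I = N <|f|^2 S_oriented>, so dividing by the
        # isotropic <|f|^2> misses the exact S increasingly with q
        pts = osc.cubic_crystal(3.5, (5, 5, 5))
        q = np.linspace(0.2, 3.0, 60)
        cyl = osc.SubunitModel.cylinder(0.17, 3.2)
        rng = np.random.default_rng(4)
        n_dirs = 3000
        u = 2 * rng.random(n_dirs) - 1
        phi = 2 * np.pi * rng.random(n_dirs)
        stheta = np.sqrt(1 - u ** 2)
        dirs = np.stack([stheta * np.cos(phi), stheta * np.sin(phi), u], axis=1)
        intensity = np.empty_like(q)
        for k, qk in enumerate(q):
            qv = qk * dirs
            f2 = np.abs(osc.amplitude(cyl, qv)) ** 2
            s_or = osc.structure_factor_oriented(pts, qv)
            intensity[k] = pts.n * np.mean(f2 * s_or)
        ff = osc.solution_form_factor(cyl, q)
        rec = osc.s_q_from_intensity(osc.ScatteringCurve(q, intensity), ff, pts.n)
        ref = osc.s_q_from_model(pts, q)
        dev = np.abs(rec.S - ref.S)
        lo = dev[q < 1.0].mean()
        hi = dev[q > 2.5].mean()
        assert hi > 3 * lo
        assert hi > 0.05

    def test_grid_mismatch_and_zero_form_factor_rejected(self):
        q = np.linspace(0.1, 2.0, 10)
        ff = osc.ScatteringCurve(q, np.ones_like(q))
        with pytest.raises(ValidationError):
            osc.s_q_from_intensity(osc.ScatteringCurve(q + 0.01, np.ones_like(q)),
                                   ff, 2)
        bad = osc.ScatteringCurve(q, np.concatenate([[0.0], np.ones(9)]))
        with pytest.raises(ValidationError, match="0.1"):
            osc.s_q_from_intensity(osc.ScatteringCurve(q, np.ones_like(q)), bad, 2)


def _gaussian_shell_rdf(rho_b=0.02, r0=3.0, s=0.1, amp=0.5, dr=0.01, r_max=8.0):
    r = np.arange(dr / 2, r_max, dr)
    g = 1.0 + amp * np.exp(-0.5 * ((r - r0) / s) ** 2)
    return osc.RDFCurve(r, g, rho_b, dr, r_max)


def _gaussian_shell_sq_closed_form(q, rho_b=0.02, r0=3.0, s=0.1, amp=0.5):
    """Analytic Fourier integral of a Gaussian shell (r0 >> s)."""
    integral = (np.sqrt(2 * np.pi) * s * np.exp(-0.5 * (q * s) ** 2)
                * (r0 * np.sin(q * r0) + s ** 2 * q * np.cos(q * r0)))
    return 1.0 + 4 * np.pi * rho_b * amp * integral / q


class TestFromGr:
    def test_uncorrelated_gas_gives_flat_structure_factor(self):
        r = np.arange(0.05, 10.0, 0.1)
        rdf = osc.RDFCurve(r, np.ones_like(r), 0.05, 0.1, 10.0)
        for method in ("simpson", "dst"):
            sq = osc.s_q_from_g_r(rdf, np.linspace(0.0, 5.0, 40), method=method)
            np.testing.assert_allclose(sq.S, 1.0, atol=1e-10)

    def test_gaussian_shell_matches_closed_form(self):
        rdf = _gaussian_shell_rdf()
        q = np.linspace(0.5, 10.0, 150)
        got = osc.s_q_from_g_r(rdf, q, method="simpson")
        ref = _gaussian_shell_sq_closed_form(q)
        np.testing.assert_allclose(got.S, ref, atol=2e-3)

    def test_dst_and_simpson_agree_on_smooth_input(self):
        rdf = _gaussian_shell_rdf()
        q = np.linspace(0.5, 8.0, 100)
        a = osc.s_q_from_g_r(rdf, q, method="simpson").S
        b = osc.s_q_from_g_r(rdf, q, method="dst").S
        assert np.max(np.abs(a - b) / np.abs(a)) < 0.01

    def test_q_zero_uses_analytic_limit(self):
        rdf = _gaussian_shell_rdf()
        sq = osc.s_q_from_g_r(rdf, np.array([0.0, 1.0]), method="simpson")
        from scipy.integrate import simpson
        ref = 1.0 + 4 * np.pi * rdf.rho_b * simpson(
            rdf.r ** 2 * (rdf.g - 1.0), x=rdf.r)
        assert sq.S[0] == pytest.approx(ref, rel=1e-10)
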