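"""Reciprocal-space grids: filling, assembly, algebra, interpolation, and
Monte Carlo orientation averaging."""
import numpy as np
import pytest

import oriscat as osc
from oriscat.errors import GridRangeError, ValidationError
from oriscat.recgrid import ReciprocalGrid


def _gaussian_grid(n_shells, q_max=4.0, width=1.3):
    """Grid of the analytic isotropic amplitude exp(-q^2 / (2 w^2))."""
    g = ReciprocalGrid(q_max, n_shells)
    for i in range(n_shells + 1):
        q = g.shell_q(i)
        g.shells[i] = np.full(g.shell_shape(i),
                              np.exp(-q * q / (2 * width ** 2)), dtype=complex)
    return g


class TestFillAndNodes:
    def test_point_scatterer_grid_is_constant(self):
        g = osc.fill_grid(osc.SubunitModel.point(2.5), 3.0, 6)
        for sh in g.shells:
            np.testing.assert_allclose(sh, 2.5)

    def test_sphere_grid_is_isotropic_per_shell(self):
        g = osc.fill_grid(osc.SubunitModel.sphere(1.5), 5.0, 10)
        for sh in g.shells:
            assert np.ptp(np.abs(sh)) < 1e-12 * max(1.0, np.abs(sh).max())

    def test_pointset_grid_matches_direct_phase_sum(self):
        # independent oracle: explicit sum of exp(i q.r) at sampled nodes
        sheet = osc.graphene_sheet(4, 4)
        g = osc.fill_grid(sheet, 30.0, 8)
        qv = g.shell_qvecs(5).reshape(-1, 3)
        ref = np.exp(1j * qv @ sheet.positions.T).sum(axis=1)
        np.testing.assert_allclose(g.shells[5].ravel(), ref, atol=1e-9)


class TestAssembly:
    def test_translation_changes_only_the_phase(self):
        m = osc.SubunitModel.sphere(1.2)
        moved = osc.AssemblyNode([(m, [osc.Placement(translation=(2.0, -1.0, 0.7))])])
        qv = np.random.default_rng(0).normal(size=(40, 3))
        a = osc.assemble_amplitude(moved, qv)
        b = osc.evaluate_amplitude(m, qv)
        np.testing.assert_allclose(np.abs(a), np.abs(b), rtol=1e-12)

    def test_two_point_scatterers_interference_closed_form(self):
        d = 1.4
        asm = osc.AssemblyNode([(osc.SubunitModel.point(1.0),
                                 [osc.Placement(translation=(0, 0, d / 2)),
                                  osc.Placement(translation=(0, 0, -d / 2))])])
        qv = np.array([[0.0, 0.0, qz] for qz in np.linspace(-4, 4, 17)])
        got = osc.assemble_amplitude(asm, qv)
        np.testing.assert_allclose(got, 2 * np.cos(qv[:, 2] * d / 2), atol=1e-12)

    def test_rotation_convention_x_then_y_then_z(self):
        # alpha = 90 about x maps the cylinder axis z onto -y; the amplitude at
        # q along y must equal the unrotated amplitude at q along z
        cyl = osc.SubunitModel.cylinder(0.3, 2.0)
        rot = osc.AssemblyNode([(cyl, [osc.Placement(rotation=(90.0, 0.0, 0.0))])])
        q = 1.7
        got = osc.assemble_amplitude(rot, np.array([0.0, q, 0.0]))
        ref = osc.evaluate_amplitude(cyl, np.array([[0.0, 0.0, -q]]))[0]
        assert got == pytest.approx(ref, rel=1e-12)

    def test_nested_assembly_equals_flat_sum(self):
        p = osc.SubunitModel.point(1.0)
        inner = osc.AssemblyNode([(p, [osc.Placement(translation=(1, 0, 0)),
                                       osc.Placement(translation=(-1, 0, 0))])])
        outer = osc.AssemblyNode([(inner, [osc.Placement(translation=(0, 0, 2)),
                                           osc.Placement(translation=(0, 0, -2))])])
        flat = osc.AssemblyNode([(p, [osc.Placement(translation=t) for t in
                                      [(1, 0, 2), (-1, 0, 2), (1, 0, -2), (-1, 0, -2)]])])
        qv = np.random.default_rng(1).normal(size=(30, 3))
        np.testing.assert_allclose(osc.assemble_amplitude(outer, qv),
                                   osc.assemble_amplitude(flat, qv), atol=1e-12)


class TestGridAlgebra:
    def test_multiply_identity_and_commutativity(self):
        a = osc.fill_grid(osc.SubunitModel.sphere(1.0), 3.0, 5)
        ones = osc.fill_grid(osc.SubunitModel.point(1.0), 3.0, 5)
        prod = osc.multiply_grids(a, ones)
        for x, y in zip(prod.shells, a.shells):
            np.testing.assert_array_equal(x, y)
        b = osc.fill_grid(osc.SubunitModel.sphere(0.5), 3.0, 5)
        ab = osc.multiply_grids(a, b)
        ba = osc.multiply_grids(b, a)
        for x, y in zip(ab.shells, ba.shells):
            np.testing.assert_array_equal(x, y)

    def test_sum_linearity_matches_union_assembly(self):
        p1 = osc.AssemblyNode([(osc.SubunitModel.point(1.0),
                                [osc.Placement(translation=(0, 0, 1.0))])])
        p2 = osc.AssemblyNode([(osc.SubunitModel.point(1.0),
                                [osc.Placement(translation=(0, 0, -1.0))])])
        union = osc.AssemblyNode([(osc.SubunitModel.point(1.0),
                                   [osc.Placement(translation=(0, 0, 1.0)),
                                    osc.Placement(translation=(0, 0, -1.0))])])
        ga = osc.sum_grids(osc.fill_grid(p1, 4.0, 6), osc.fill_grid(p2, 4.0, 6))
        gu = osc.fill_grid(union, 4.0, 6)
        for x, y in zip(ga.shells, gu.shells):
            np.testing.assert_allclose(x, y, atol=1e-12)

    def test_layout_mismatch_rejected(self):
        a = osc.fill_grid(osc.SubunitModel.point(1.0), 3.0, 5)
        b = osc.fill_grid(osc.SubunitModel.point(1.0), 3.0, 6)
        with pytest.raises(ValidationError):
            osc.sum_grids(a, b)


class TestInterpolation:
    def test_exact_at_grid_nodes(self):
        g = osc.fill_grid(osc.SubunitModel.sphere(1.5), 5.0, 9)
        for i in (1, 4, 8, 9):
            qv = g.shell_qvecs(i).reshape(-1, 3)
            np.testing.assert_allclose(g.interpolate(qv), g.shells[i].ravel(),
                                       atol=1e-12)

    def test_out_of_range_rejected(self):
        g = osc.fill_grid(osc.SubunitModel.sphere(1.0), 2.0, 4)
        with pytest.raises(GridRangeError):
            g.interpolate(np.array([0.0, 0.0, 2.5]))

    def test_isotropic_grid_interpolation_is_direction_independent(self):
        g = _gaussian_grid(12)
        rng = np.random.default_rng(3)
        q = 2.37
        dirs = rng.normal(size=(50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        vals = g.interpolate(q * dirs)
        assert np.ptp(vals.real) < 1e-10
        assert np.allclose(vals.imag, 0.0)

    def test_error_shrinks_at_least_fourfold_when_shells_double(self):
        rng = np.random.default_rng(8)
        dirs = rng.normal(size=(300, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        q = 0.2 + 3.5 * rng.random(300)
        qv = q[:, None] * dirs
        ref = np.exp(-q * q / (2 * 1.3 ** 2))
        errs = []
        for n_shells in (16, 32, 64):
            g = _gaussian_grid(n_shells)
            errs.append(np.abs(g.interpolate(qv).real - ref).max())
        assert errs[1] <= errs[0] / 4
        assert errs[2] <= errs[1] / 4


class TestOrientationAverage:
    def test_isotropic_source_equals_squared_amplitude(self):
        m = osc.SubunitModel.sphere(1.5)
        q = np.linspace(0.1, 4.0, 30)
        curve = osc.orientation_average(m, q, rel_tol=1e-3, seed=1)
        ref = osc.solution_form_factor(m, q).I
        np.testing.assert_allclose(curve.I, ref, rtol=1e-9)
        assert curve.metadata["converged"]

    def test_two_point_debye_closed_form(self):
        d = 2.2
        asm = osc.AssemblyNode([(osc.SubunitModel.point(1.0),
                                 [osc.Placement(translation=(0, 0, d / 2)),
                                  osc.Placement(translation=(0, 0, -d / 2))])])
        q = np.linspace(0.0, 5.0, 26)
        curve = osc.orientation_average(asm, q, rel_tol=2e-4,
                                        max_samples=2 ** 16, seed=2)
        ref = 2.0 * (1.0 + np.sinc(q * d / np.pi))
        resid = np.linalg.norm(curve.I - ref) / np.linalg.norm(ref)
        assert resid < 0.02

    def test_crystal_average_matches_debye_sum_within_mc_error(self):
        pts = osc.cubic_crystal(3.5, (5, 5, 5))
        q = np.array([0.5, 1.0, 1.8, 2.5])
        curve = osc.orientation_average(pts, q, rel_tol=1e-3,
                                        max_samples=2 ** 14, seed=6)
        ref = osc.s_q_from_model(pts, q).S * pts.n
        # Monte Carlo relative accuracy at this budget; 3 sigma-equivalent band
        np.testing.assert_allclose(curve.I, ref, rtol=0.15)

    def test_global_translation_leaves_average_unchanged(self):
        pts = osc.point_helix(1.0, 0.4, 40.0, 8)
        moved = osc.PointSet(pts.positions + np.array([3.0, -2.0, 5.0]))
        q = np.linspace(0.2, 4.0, 15)
        a = osc.orientation_average(pts, q, rel_tol=5e-4, max_samples=2 ** 14, seed=9)
        b = osc.orientation_average(moved, q, rel_tol=5e-4, max_samples=2 ** 14, seed=9)
        assert np.linalg.norm(a.I - b.I) / np.linalg.norm(a.I) < 0.05

    def test_unconverged_run_is_flagged_not_raised(self):
        pts = osc.cubic_crystal(3.5, (4, 4, 4))
        curve = osc.orientation_average(pts, np.array([1.795]), rel_tol=1e-9,
                                        max_samples=512, seed=0)
        assert curve.metadata["converged"] is False
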