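"""B-spline basis matrices, surface evaluation, polynomial patches, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import BSpline
from scipy.spatial import ConvexHull

from cardioshape.bspline import (
    BSplineSurface,
    basis_matrix,
    evaluate_global,
    evaluate_surface,
    fit_surface_to_landmark_grid,
    tessellate,
    to_polynomial_patches,
)
from cardioshape.shape_model import LandmarkShape
from cardioshape.synthetic import sphere_landmark_grid, unit_cube_surface


def cox_de_boor(surface: BSplineSurface, u: float, v: float) -> np.ndarray:
    """Independent oracle: tensor-product Cox-de Boor recursion via scipy."""
    k1, k2 = surface.order_u, surface.order_v
    nu, nv, _ = surface.control_net.shape
    tu = np.arange(nu + k1 + 1, dtype=float)
    tv = np.arange(nv + k2 + 1, dtype=float)
    x = k1 + u * (nu - k1)
    y = k2 + v * (nv - k2)
    out = np.zeros(3)
    for c in range(3):
        along_u = [BSpline(tu, surface.control_net[:, j, c], k1,
                           extrapolate=False)(x) for j in range(nv)]
        out[c] = BSpline(tv, np.asarray(along_u), k2, extrapolate=False)(y)
    return out


class TestBasisMatrix:
    def test_linear_interpolates_first_point(self):
        M = basis_matrix(1)
        assert np.array_equal(M, [[1.0, 0.0], [-1.0, 1.0]])
        p = np.array([3.0, 7.0])
        assert (np.array([1.0, 0.0]) @ M @ p) == 3.0

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_partition_of_unity(self, order):
        M = basis_matrix(order)
        for t in np.linspace(0, 1, 11):
            T = t ** np.arange(order + 1)
            assert (T @ M).sum() == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_entries_have_denominator_two(self):
        M = basis_matrix(2)
        assert np.allclose(2.0 * M, np.round(2.0 * M))
        # verified against direct Cox-de Boor evaluation of a quadratic curve
        rng = np.random.default_rng(1)
        ctrl = rng.normal(size=5)
        knots = np.arange(8, dtype=float)
        sp = BSpline(knots, ctrl, 2, extrapolate=False)
        for t in np.linspace(0, 1, 50):
            T = t ** np.arange(3)
            ours = T @ M @ ctrl[:3]
            assert ours == pytest.approx(float(sp(2.0 + t)), abs=1e-12)

    def test_unsupported_order_names_supported_set(self):
        with pytest.raises(ValueError, match="1, 2, 3"):
            basis_matrix(5)


class TestEvaluate:
    def test_constant_net_everywhere_constant(self):
        p = np.array([2.0, -1.0, 5.0])
        net = np.tile(p, (6, 6, 1))
        surf = BSplineSurface(net, 3, 3)
        for t, w in [(0, 0), (0.3, 0.8), (1, 1)]:
            assert np.allclose(evaluate_surface(surf, t, w, (1, 1)), p, atol=1e-12)

    def test_planar_net_stays_planar(self, rng):
        net = rng.normal(size=(7, 6, 3))
        net[:, :, 2] = 0.0
        surf = BSplineSurface(net, 3, 3)
        pts = evaluate_global(surf, rng.random(50), rng.random(50))
        assert np.abs(pts[:, 2]).max() < 1e-12

    def test_matrix_form_matches_cox_de_boor(self, rng):
        net = rng.normal(size=(8, 7, 3))
        surf = BSplineSurface(net, 3, 3)
        for _ in range(100):
            u, v = rng.random(2)
            ours = evaluate_global(surf, u, v)[0]
            assert np.abs(ours - cox_de_boor(surf, u, v)).max() < 1e-10

    @pytest.mark.parametrize("orders", [(1, 1), (2, 2), (2, 3), (3, 3)])
    def test_all_orders_match_oracle(self, rng, orders):
        k1, k2 = orders
        net = rng.normal(size=(k1 + 4, k2 + 3, 3))
        surf = BSplineSurface(net, k1, k2)
        for _ in range(20):
            u, v = rng.random(2)
            assert np.abs(evaluate_global(surf, u, v)[0]
                          - cox_de_boor(surf, u, v)).max() < 1e-10

    def test_span_out_of_range(self, rng):
        surf = BSplineSurface(rng.normal(size=(6, 6, 3)), 3, 3)
        with pytest.raises(IndexError):
            evaluate_surface(surf, 0.5, 0.5, (10, 0))

    def test_convex_hull_property(self, rng):
        net = rng.normal(size=(7, 7, 3))
        surf = BSplineSurface(net, 3, 3)
        for _ in range(8):
            su = rng.integers(0, surf.n_spans_u)
            sv = rng.integers(0, surf.n_spans_v)
            local = surf.local_net(int(su), int(sv)).reshape(-1, 3)
            hull = ConvexHull(local)
            pt = evaluate_surface(surf, rng.random(), rng.random(), (int(su), int(sv)))
            viol = (hull.equations[:, :3] @ pt + hull.equations[:, 3]).max()
            assert viol < 1e-9

    def test_affine_equivariance(self, rng):
        net = rng.normal(size=(6, 7, 3))
        surf = BSplineSurface(net, 3, 3)
        A = rng.normal(size=(3, 3))
        off = rng.normal(size=3)
        surf2 = surf.transformed(A, off)
        u, v = rng.random(20), rng.random(20)
        lhs = evaluate_global(surf2, u, v)
        rhs = evaluate_global(surf, u, v) @ A.T + off
        assert np.abs(lhs - rhs).max() < 1e-10


class TestPolynomialPatches:
    def test_constant_net_single_coefficient(self):
        p = np.array([1.0, 2.0, 3.0])
        surf = BSplineSurface(np.tile(p, (5, 5, 1)), 3, 3)
        for patch in to_polynomial_patches(surf):
            assert np.allclose(patch.coeffs[0, 0], p, atol=1e-12)
            rest = patch.coeffs.copy()
            rest[0, 0] = 0.0
            assert np.abs(rest).max() < 1e-12

    def test_linear_in_u_only_degree_bound(self):
        # control net affine in the u index: surface linear in t
        iu = np.arange(7, dtype=float)
        net = np.zeros((7, 6, 3))
        net[:, :, 0] = iu[:, None]
        net[:, :, 1] = 2.0
        surf = BSplineSurface(net, 3, 3)
        for patch in to_polynomial_patches(surf):
            assert np.abs(patch.coeffs[2:, :, :]).max() < 1e-12

    def test_patch_count_is_span_product(self, rng):
        surf = BSplineSurface(rng.normal(size=(9, 7, 3)), 3, 3)
        patches = to_polynomial_patches(surf)
        assert len(patches) == surf.n_spans_u * surf.n_spans_v

    def test_patch_evaluation_matches_surface(self, rng):
        surf = BSplineSurface(rng.normal(size=(7, 7, 3)), 3, 3)
        for patch in to_polynomial_patches(surf)[:6]:
            for _ in range(25):
                t, w = rng.random(2)
                direct = evaluate_surface(surf, t, w, patch.patch_index)
                assert np.abs(patch.evaluate(t, w) - direct).max() < 1e-9


class TestFitSurface:
    def test_round_trip_reproduces_samples(self, rng):
        grid = sphere_landmark_grid(2.0, 24, 17)
        first = fit_surface_to_landmark_grid(grid, n_ctrl_u=12, n_ctrl_v=12)
        rows, cols = grid.grid_dims
        us = np.arange(cols) / cols
        vs = (np.arange(rows) + 1.0) / (rows + 1.0)
        samples = np.stack([evaluate_global(first, us, np.full_like(us, v))
                            for v in vs]).reshape(-1, 3)
        refit = fit_surface_to_landmark_grid(
            LandmarkShape(samples, grid_dims=grid.grid_dims),
            n_ctrl_u=12, n_ctrl_v=12)
        assert refit.fit_rms < 1e-8

    def test_planar_grid_fits_planar_surface(self, rng):
        xs, ys = np.meshgrid(np.linspace(0, 4, 10), np.linspace(0, 3, 12),
                             indexing="ij")
        pts = np.stack([xs, ys, np.zeros_like(xs)], axis=-1).reshape(-1, 3)
        grid = LandmarkShape(pts, grid_dims=(10, 12))
        surf = fit_surface_to_landmark_grid(grid, closed_u=False, pole_caps=False,
                                            n_ctrl_u=8, n_ctrl_v=7)
        samp = evaluate_global(surf, rng.random(100), rng.random(100))
        assert np.abs(samp[:, 2]).max() < 1e-9

    def test_residual_non_increasing_with_resolution(self):
        grid = sphere_landmark_grid(1.0, 32, 24)
        rms = [fit_surface_to_landmark_grid(grid, n_ctrl_u=n, n_ctrl_v=n).fit_rms
               for n in (8, 12, 16)]
        assert rms[0] >= rms[1] >= rms[2]

    def test_underdetermined_raises(self):
        grid = sphere_landmark_grid(1.0, 8, 6)
        with pytest.raises(ValueError, match="fewer control points"):
            fit_surface_to_landmark_grid(grid, n_ctrl_u=16, n_ctrl_v=20)

    def test_missing_grid_dims_raises(self, rng):
        shape = LandmarkShape(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="grid_dims"):
            fit_surface_to_landmark_grid(shape)


class TestTessellate:
    def test_closed_capped_surface_is_watertight_sphere(self):
        grid = sphere_landmark_grid(1.0, 24, 18)
        surf = fit_surface_to_landmark_grid(grid, n_ctrl_u=10, n_ctrl_v=10)
        mesh = tessellate(surf, 24, 20)
        assert mesh.watertight
        assert mesh.euler_characteristic == 2

    def test_vertex_count_formula(self):
        # closed-u + pole caps: nu * (nv - 2) interior ring vertices + 2 poles,
        # with the requested resolution rounded up to a span multiple
        grid = sphere_landmark_grid(1.0, 24, 18)
        surf = fit_surface_to_landmark_grid(grid, n_ctrl_u=10, n_ctrl_v=10)
        res_u, res_v = 24, 20
        Su, Sv = surf.n_spans_u, surf.n_spans_v
        nu = Su * int(np.ceil(res_u / Su))
        nv = Sv * int(np.ceil((res_v - 1) / Sv)) + 1
        mesh = tessellate(surf, res_u, res_v)
        assert len(mesh.vertices) == nu * (nv - 2) + 2

    def test_refinement_reduces_distance_to_dense_samples(self, rng):
        grid = sphere_landmark_grid(1.0, 24, 18)
        surf = fit_surface_to_landmark_grid(grid, n_ctrl_u=10, n_ctrl_v=10)
        samples = evaluate_global(surf, rng.random(200), rng.random(200))

        def max_nearest(mesh):
            from scipy.spatial import cKDTree

            return cKDTree(mesh.vertices).query(samples)[0].max()

        coarse = max_nearest(tessellate(surf, 12, 12))
        fine = max_nearest(tessellate(surf, 24, 24))
        assert fine < coarse

    def test_resolution_validation(self):
        with pytest.raises(ValueError):
            tessellate(unit_cube_surface(), 1, 8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), t=st.floats(0, 1), w=st.floats(0, 1))
def test_partition_of_unity_any_constant_net(seed, t, w):
    """Evaluating a constant control net returns the constant for any (t, w)."""
    rng = np.random.default_rng(seed)
    p = rng.normal(size=3) * 10
    surf = BSplineSurface(np.tile(p, (6, 5, 1)), 3, 3)
    pt = evaluate_global(surf, t, w)[0]
    assert np.abs(pt - p).max() < 1e-12
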