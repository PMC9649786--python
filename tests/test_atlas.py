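"""Kernel machinery, geodesic shooting, varifold metric and atlas estimation."""

import warnings

import numpy as np
import pytest

from lvshape.atlas import (
    Atlas,
    ControlPointSet,
    MomentaField,
    atlas_residual,
    build_control_grid,
    estimate_atlas,
    load_atlas,
    save_atlas,
    shoot_and_flow,
    varifold_distance,
    _varifold_grad_vertices,
    _flow_forward,
    _flow_backward,
)
from lvshape.kernels import gaussian_kernel_matrix
from lvshape.mesh import TriangleMesh

from .conftest import copy_mesh, make_icosphere


class TestKernel:
    def test_closed_form_values(self):
        a = np.array([[0.0, 0.0, 0.0]])
        assert gaussian_kernel_matrix(a, a, 5.0)[0, 0] == pytest.approx(1.0)
        b = np.array([[5.0, 0.0, 0.0]])  # distance = width
        assert gaussian_kernel_matrix(a, b, 5.0)[0, 0] == pytest.approx(np.exp(-1))

    def test_psd_on_random_points(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 10, (40, 3))
        K = gaussian_kernel_matrix(pts, pts, 7.0)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            gaussian_kernel_matrix(np.zeros((1, 3)), np.zeros((1, 3)), 0.0)


class TestControlGrid:
    def test_box_70_70_90(self):
        # 70x70x90 box, width 35: ceil(extent/35)+1 = 3,3,4 points per axis
        verts = np.array([[0, 0, 0], [70, 70, 90]], dtype=float)
        faces = np.array([[0, 1, 1]])  # placeholder topology; only bbox matters
        m = TriangleMesh(verts, np.array([[0, 0, 1]]))
        m = TriangleMesh(np.array([[0.0, 0, 0], [70, 0, 0], [0, 70, 90]]), np.array([[0, 1, 2]]))
        grid = build_control_grid([m], kernel_width=35.0, margin=0.0)
        assert grid.n_points == 3 * 3 * 4

    def test_minimum_two_per_axis(self, unit_sphere):
        grid = build_control_grid([unit_sphere], kernel_width=50.0, margin=0.0)
        assert grid.n_points == 8

    def test_spacing_equals_width(self, unit_sphere):
        grid = build_control_grid([unit_sphere], kernel_width=0.8, margin=0.2)
        xs = np.unique(grid.points[:, 0])
        assert np.allclose(np.diff(xs), 0.8)


class TestShooting:
    def test_zero_momenta_identity(self, sphere25_coarse):
        cps = build_control_grid([sphere25_coarse], 35.0, 10.0)
        mom = MomentaField(np.zeros((cps.n_points, 3)), cps)
        out = shoot_and_flow(sphere25_coarse, cps, mom)
        assert np.array_equal(out.vertices, sphere25_coarse.vertices)
        assert np.array_equal(out.faces, sphere25_coarse.faces)

    def test_small_momentum_linearisation(self, sphere25_coarse):
        # one control point at the origin, tiny momentum: displacement of a
        # vertex v is exp(-|v-c|^2/w^2) * p to first order
        cps = ControlPointSet(np.array([[0.0, 0.0, 0.0]]), 20.0)
        p = np.array([[1e-3, 0.0, 0.0]])
        mom = MomentaField(p, cps)
        out = shoot_and_flow(sphere25_coarse, cps, mom, n_steps=10)
        disp = out.vertices - sphere25_coarse.vertices
        r2 = (sphere25_coarse.vertices**2).sum(axis=1)
        expected = np.exp(-r2 / 20.0**2)[:, None] * p
        assert np.allclose(disp, expected, rtol=0.01, atol=1e-9)

    def test_approximate_inverse(self, sphere25_coarse):
        cps = build_control_grid([sphere25_coarse], 35.0, 10.0)
        rng = np.random.default_rng(1)
        p = rng.normal(0, 0.3, (cps.n_points, 3))
        fwd = shoot_and_flow(sphere25_coarse, cps, MomentaField(p, cps))
        back = shoot_and_flow(fwd, cps, MomentaField(-p, cps))
        fwd_disp = np.linalg.norm(fwd.vertices - sphere25_coarse.vertices, axis=1).max()
        err = np.linalg.norm(back.vertices - sphere25_coarse.vertices, axis=1).max()
        assert fwd_disp > 0.5  # the deformation is non-trivial
        assert err < 0.05 * fwd_disp

    def test_nonfinite_momenta_rejected(self, sphere25_coarse):
        cps = ControlPointSet(np.zeros((1, 3)), 10.0)
        with pytest.raises(ValueError):
            MomentaField(np.array([[np.nan, 0, 0]]), cps)


class TestVarifold:
    def test_identity_and_symmetry(self, sphere25_coarse):
        other = make_icosphere(26.0, 2)
        d_self = varifold_distance(sphere25_coarse, sphere25_coarse)
        d_ab = varifold_distance(sphere25_coarse, other)
        d_ba = varifold_distance(other, sphere25_coarse)
        assert abs(d_self) <= 1e-8 * d_ab
        assert d_ab == pytest.approx(d_ba, rel=1e-10)
        assert d_ab > 0

    def test_monotonicity_and_bruteforce(self):
        s20 = make_icosphere(20.0, 1)
        s21 = make_icosphere(21.0, 1)
        s30 = make_icosphere(30.0, 1)
        assert varifold_distance(s20, s21) < varifold_distance(s20, s30)

        # brute-force double loop oracle on tiny meshes
        def brute(a, b, w):
            def rep(m):
                va, vb, vc = m.face_corners()
                cent = (va + vb + vc) / 3
                N = 0.5 * np.cross(vb - va, vc - va)
                ar = np.linalg.norm(N, axis=1)
                return cent, N / ar[:, None], ar

            ca, na, aa = rep(a)
            cb, nb, ab_ = rep(b)

            def inner(c1, n1, a1, c2, n2, a2):
                tot = 0.0
                for i in range(len(c1)):
                    for j in range(len(c2)):
                        k = np.exp(-((c1[i] - c2[j]) ** 2).sum() / w**2)
                        tot += k * (n1[i] @ n2[j]) ** 2 * a1[i] * a2[j]
                return tot

            return (
                inner(ca, na, aa, ca, na, aa)
                - 2 * inner(ca, na, aa, cb, nb, ab_)
                + inner(cb, nb, ab_, cb, nb, ab_)
            )

        assert varifold_distance(s20, s21, 11.0) == pytest.approx(
            brute(s20, s21, 11.0), rel=1e-9
        )

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        F = np.array([[0, 1, 2], [1, 3, 2], [2, 3, 4]])
        V = rng.normal(0, 3, (5, 3))
        target = TriangleMesh(rng.normal(0, 3, (5, 3)), F)
        mesh = TriangleMesh(V, F)
        _, grad = _varifold_grad_vertices(mesh, target, 4.0)
        eps = 1e-6
        for i in range(5):
            for k in range(3):
                vp, vm = V.copy(), V.copy()
                vp[i, k] += eps
                vm[i, k] -= eps
                num = (
                    varifold_distance(TriangleMesh(vp, F), target, 4.0)
                    - varifold_distance(TriangleMesh(vm, F), target, 4.0)
                ) / (2 * eps)
                assert grad[i, k] == pytest.approx(num, abs=1e-5 * max(1, abs(num)))


def test_flow_gradients_match_finite_differences():
    """Reverse-mode sweep through the Hamiltonian flow vs finite differences."""
    rng = np.random.default_rng(5)
    x0 = rng.normal(0, 2, (6, 3))
    c0 = rng.normal(0, 2, (4, 3))
    p0 = rng.normal(0, 0.3, (4, 3))
    g = rng.normal(0, 1, (6, 3))
    w = 2.0
    traj = _flow_forward(x0, c0, p0, w, 5)
    gx0, gp0 = _flow_backward(traj, w, g)

    def value(x, p):
        return (_flow_forward(x, c0, p, w, 5)[-1][0] * g).sum()

    eps = 1e-6
    for arr, grad, which in ((x0, gx0, "x"), (p0, gp0, "p")):
        for i in range(arr.shape[0]):
            for k in range(3):
                ap, am = arr.copy(), arr.copy()
                ap[i, k] += eps
                am[i, k] -= eps
                if which == "x":
                    num = (value(ap, p0) - value(am, p0)) / (2 * eps)
                else:
                    num = (value(x0, ap) - value(x0, am)) / (2 * eps)
                assert grad[i, k] == pytest.approx(num, abs=1e-6 * max(1, abs(num)))


class TestEstimateAtlas:
    def test_identical_population(self, sphere25_coarse):
        meshes = [copy_mesh(sphere25_coarse, f"s{i}") for i in range(5)]
        atl = estimate_atlas(meshes, max_iter=10)
        grid_scale = 35.0
        for mom in atl.subject_momenta:
            assert np.linalg.norm(mom.momenta) < 1e-3 * grid_scale
        # template within 0.5 mm of the sphere
        r = np.linalg.norm(atl.template.vertices, axis=1)
        assert np.abs(r - 25.0).max() < 0.5

    def test_too_few_subjects(self, sphere25_coarse):
        with pytest.raises(ValueError):
            estimate_atlas([sphere25_coarse, sphere25_coarse])

    def test_loss_trace_monotone_and_residuals(self):
        m18, m22 = make_icosphere(18.0, 1), make_icosphere(22.0, 1)
        meshes = [
            copy_mesh(m18, "a"), copy_mesh(m22, "b"), copy_mesh(m18, "c"),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            atl = estimate_atlas(meshes, max_iter=12)
        lt = atl.loss_trace
        assert all(b <= a + 1e-12 for a, b in zip(lt, lt[1:]))
        # deformation improves the fit for every subject vs undeformed template
        res = atlas_residual(atl, meshes)
        for mom, m in zip(atl.subject_momenta, meshes):
            from lvshape.remesh import closest_point_on_surface

            _, d0 = closest_point_on_surface(atl.template.vertices, m)
            assert res[mom.subject_id]["mean_mm"] <= d0.mean() + 1e-9

    def test_determinism(self):
        m = make_icosphere(20.0, 1)
        meshes = [
            TriangleMesh(m.vertices * s, m.faces, f"m{i}")
            for i, s in enumerate((0.9, 1.0, 1.1))
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a1 = estimate_atlas([copy_mesh(x, x.label) for x in meshes], max_iter=4, seed=3)
            a2 = estimate_atlas([copy_mesh(x, x.label) for x in meshes], max_iter=4, seed=3)
        assert a1.loss_trace == a2.loss_trace  # bitwise identical

    def test_residual_permutation_invariance(self):
        m = make_icosphere(20.0, 1)
        meshes = [
            TriangleMesh(m.vertices * s, m.faces, f"m{i}")
            for i, s in enumerate((0.95, 1.0, 1.05))
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            atl = estimate_atlas(meshes, max_iter=4)
        res1 = atlas_residual(atl, meshes)
        res2 = atlas_residual(atl, meshes[::-1])
        assert res1 == res2

    def test_mismatched_subject_id(self):
        m = make_icosphere(20.0, 1)
        meshes = [copy_mesh(m, f"m{i}") for i in range(3)]
        atl = estimate_atlas(meshes, max_iter=3)
        bad = [copy_mesh(m, "other")]
        with pytest.raises(ValueError):
            atlas_residual(atl, bad)


def test_atlas_serialisation_roundtrip(tmp_path):
    m = make_icosphere(20.0, 1)
    meshes = [
        TriangleMesh(m.vertices * s, m.faces, f"m{i}")
        for i, s in enumerate((0.95, 1.0, 1.05))
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        atl = estimate_atlas(meshes, max_iter=3)
    save_atlas(atl, tmp_path / "atlas")
    back = load_atlas(tmp_path / "atlas")
    assert back.subject_ids == atl.subject_ids
    assert np.allclose(back.momenta_array(), atl.momenta_array(), atol=1e-6)
    assert np.allclose(back.template.vertices, atl.template.vertices, atol=1e-5)
    assert back.loss_trace == atl.loss_trace
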