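"""Profile models, pose/shape update, and the iterative model-to-image fit."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cardioshape.fitting import (
    ImageVolume,
    build_profile_models,
    fit,
    grid_normals,
    initialize_pose,
    search_profile,
    update_pose_and_shape,
)
from cardioshape.shape_model import (
    LandmarkShape,
    SimilarityTransform,
    generate_shape,
    procrustes_similarity,
)
from cardioshape.synthetic import (
    PhantomSpec,
    make_image_volume,
    make_ventricle_shape,
    sphere_landmark_grid,
)


@pytest.fixture(scope="module")
def rendered_case():
    """Noise-free phantom rendering with ground-truth landmarks."""
    spec = PhantomSpec(seed=1)
    endo, epi = make_ventricle_shape(spec)
    img, gt = make_image_volume(endo, epi, resolution=44, noise_sigma=0.0,
                                blur_sigma=1.0, seed=0)
    return img, gt


@pytest.fixture(scope="module")
def trained_profiles(rendered_case):
    img, gt = rendered_case
    return build_profile_models([img], [gt], k=4)


class TestImageVolume:
    def test_validation(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4, 4)), spacing=[1, 0, 1])
        with pytest.raises(ValueError):
            ImageVolume(np.full((4, 4, 4), np.nan))

    def test_trilinear_sampling(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 8.0
        img = ImageVolume(data, spacing=[2.0, 2.0, 2.0])
        assert img.sample(np.array([[2.0, 2.0, 2.0]]))[0] == pytest.approx(8.0)
        assert img.sample(np.array([[1.0, 2.0, 2.0]]))[0] == pytest.approx(4.0)


class TestGridNormals:
    def test_sphere_normals_point_outward(self):
        grid = sphere_landmark_grid(3.0, 16, 12)
        n = grid_normals(grid)
        radial = grid.points / np.linalg.norm(grid.points, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", n, radial)
        assert dots.min() > 0.2
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-12)

    def test_requires_grid(self, rng):
        with pytest.raises(ValueError, match="grid_dims"):
            grid_normals(LandmarkShape(rng.normal(size=(10, 3))))


class TestProfileModel:
    def test_profile_length_and_peak_at_boundary(self, rendered_case):
        img, gt = rendered_case
        pm = build_profile_models([img], [gt], k=4)
        assert pm.mean_profiles.shape == (gt.n, 9)
        # the generator puts the blood/myocardium edge at the landmarks, so
        # the mean gradient profile peaks at (or next to) the centre offset
        peaks = np.abs(pm.mean_profiles).argmax(axis=1)
        assert (np.abs(peaks - 4) <= 1).mean() > 0.9

    def test_identical_images_leave_only_ridge(self, rendered_case):
        img, gt = rendered_case
        pm = build_profile_models([img, img, img], [gt, gt, gt], k=3)
        # zero sample covariance: the inverse is (1/ridge) * identity
        for i in (0, gt.n // 2):
            inv = pm.cov_inv[i]
            off_diag = inv - np.diag(np.diag(inv))
            assert np.abs(off_diag).max() < 1e-6 * np.abs(np.diag(inv)).max()

    def test_covariance_symmetric_positive_definite(self, trained_profiles):
        for i in range(0, trained_profiles.mean_profiles.shape[0], 37):
            inv = trained_profiles.cov_inv[i]
            assert np.allclose(inv, inv.T, atol=1e-9)
            assert np.all(np.linalg.eigvalsh(inv) > 0)

    def test_unpaired_inputs_rejected(self, rendered_case):
        img, gt = rendered_case
        with pytest.raises(ValueError, match="paired"):
            build_profile_models([img], [gt, gt])


class TestSearchProfile:
    def test_recovers_known_edge_offset(self, rendered_case, trained_profiles):
        img, gt = rendered_case
        normals = grid_normals(gt)
        pm = trained_profiles
        hits = 0
        idxs = range(10, gt.n, 17)
        for i in idxs:
            start = gt.points[i] - 3.0 * pm.step * normals[i]
            _, off = search_profile(img, start, normals[i], pm.mean_profiles[i],
                                    pm.cov_inv[i], m=8, step=pm.step)
            hits += off == 3
        assert hits / len(list(idxs)) > 0.8

    def test_on_boundary_returns_zero_offset(self, rendered_case, trained_profiles):
        img, gt = rendered_case
        normals = grid_normals(gt)
        pm = trained_profiles
        offs = []
        for i in range(10, gt.n, 29):
            _, off = search_profile(img, gt.points[i], normals[i],
                                    pm.mean_profiles[i], pm.cov_inv[i],
                                    m=8, step=pm.step)
            offs.append(off)
        assert np.median(np.abs(offs)) == 0

    def test_tie_break_is_deterministic_toward_zero(self, trained_profiles):
        # uniform image: every offset scores identically, so zero must win
        flat = ImageVolume(np.full((12, 12, 12), 5.0))
        pm = trained_profiles
        _, off = search_profile(flat, np.array([6.0, 6.0, 6.0]),
                                np.array([0.0, 0.0, 1.0]),
                                pm.mean_profiles[0], pm.cov_inv[0],
                                m=8, step=1.0)
        assert off == 0

    def test_m_smaller_than_k_rejected(self, trained_profiles):
        pm = trained_profiles
        with pytest.raises(ValueError, match=">="):
            search_profile(ImageVolume(np.zeros((5, 5, 5))), np.zeros(3),
                           np.array([0.0, 0.0, 1.0]), pm.mean_profiles[0],
                           pm.cov_inv[0], m=2, step=1.0)


class TestUpdatePoseAndShape:
    def test_exact_model_round_trip(self, rng, small_model):
        worst = 0.0
        for i in range(20):
            b0 = rng.normal(0, 0.5, small_model.n_modes) * np.sqrt(
                small_model.eigenvalues)
            T0 = SimilarityTransform(
                scale=float(np.exp(rng.normal(0, 0.3))) * 200.0,
                rotation=Rotation.random(rng=rng).as_matrix(),
                translation=rng.normal(0, 30, 3),
            )
            X = T0.apply_shape(generate_shape(small_model, b0))
            pose, b, resid = update_pose_and_shape(small_model, X)
            worst = max(worst, resid)
            sig = np.sqrt(small_model.eigenvalues)
            assert np.abs(b - b0).max() < 0.05 * sig.max()
        assert worst < 1e-8

    def test_mean_candidates_give_zero_parameters(self, small_model):
        pose, b, resid = update_pose_and_shape(small_model, small_model.mean)
        assert np.abs(b).max() < 1e-10
        assert resid < 1e-20
        assert pose.scale == pytest.approx(1.0, rel=1e-8)

    def test_residual_not_worse_than_pose_only(self, rng, small_model):
        noisy = LandmarkShape(small_model.mean.points * 150.0
                              + rng.normal(0, 2.0, (small_model.n_landmarks, 3)))
        pose0 = procrustes_similarity(small_model.mean.points, noisy.points)
        resid0 = float(((noisy.points - pose0.apply(small_model.mean.points)) ** 2).sum())
        _, _, resid = update_pose_and_shape(small_model, noisy)
        assert resid <= resid0 + 1e-9

    def test_degenerate_candidates_rejected(self, small_model):
        flat = LandmarkShape(np.zeros((small_model.n_landmarks, 3)) + 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            update_pose_and_shape(small_model, flat)


class TestInitializePose:
    def test_bright_ellipsoid_centroid(self):
        shape = (32, 32, 32)
        idx = np.indices(shape, dtype=float)
        center = np.array([18.0, 14.0, 16.0])
        r2 = ((idx[0] - center[0]) / 8) ** 2 + ((idx[1] - center[1]) / 6) ** 2 \
            + ((idx[2] - center[2]) / 10) ** 2
        img = ImageVolume(np.where(r2 < 1.0, 200.0, 20.0), spacing=[1.5, 1.5, 1.5])
        init = initialize_pose(img)
        assert np.abs(init.translation / 1.5 - center).max() < 2.0
        assert init.scale > 0

    def test_translation_equivariance(self):
        data = np.full((24, 24, 24), 10.0)
        data[4:10, 6:12, 8:14] = 200.0
        a = initialize_pose(ImageVolume(data, origin=[0.0, 0.0, 0.0]))
        b = initialize_pose(ImageVolume(data, origin=[5.0, -3.0, 2.0]))
        assert np.allclose(b.translation - a.translation, [5.0, -3.0, 2.0], atol=1e-9)

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            initialize_pose(ImageVolume(np.full((8, 8, 8), 3.0)))


@pytest.fixture(scope="module")
def asm_setup(phantom_spec, small_training, small_model):
    imgs, lms = [], []
    for i in range(4):
        endo, epi = make_ventricle_shape(phantom_spec,
                                         b_true=small_training.b_true[i])
        img, gt = make_image_volume(endo, epi, resolution=44,
                                    noise_sigma=5.0, blur_sigma=1.0,
                                    seed=500 + i)
        imgs.append(img)
        lms.append(gt)
    profiles = build_profile_models(imgs, lms, k=4)
    return small_model, profiles


class TestFit:
    def _render_case(self, phantom_spec, small_training, i):
        endo, epi = make_ventricle_shape(phantom_spec,
                                         b_true=small_training.b_true[20 + i])
        return make_image_volume(endo, epi, resolution=44, noise_sigma=5.0,
                                 blur_sigma=1.0, seed=900 + i)

    def test_recovers_phantom_within_one_voxel(self, asm_setup, phantom_spec,
                                               small_training):
        model, profiles = asm_setup
        img, gt = self._render_case(phantom_spec, small_training, 0)
        true_pose = procrustes_similarity(model.mean.points, gt.points)
        rngp = np.random.default_rng(77)
        dR = Rotation.from_rotvec(
            np.deg2rad(5.0) * rngp.normal(size=3) / np.sqrt(3)).as_matrix()
        init = SimilarityTransform(true_pose.scale, dR @ true_pose.rotation,
                                   true_pose.translation
                                   + rngp.normal(0, 5.0 / np.sqrt(3), 3))
        res = fit(model, profiles, img, init, max_iter=20, m=8, ground_truth=gt)
        assert res.landmark_error < float(img.spacing[0])

    def test_true_pose_converges_quickly(self, asm_setup, phantom_spec,
                                         small_training):
        model, profiles = asm_setup
        img, gt = self._render_case(phantom_spec, small_training, 1)
        init = procrustes_similarity(model.mean.points, gt.points)
        res = fit(model, profiles, img, init, max_iter=10, m=8)
        assert res.converged
        assert res.iterations <= 2

    def test_zero_iterations_returns_init(self, asm_setup, phantom_spec,
                                          small_training):
        model, profiles = asm_setup
        img, gt = self._render_case(phantom_spec, small_training, 2)
        init = procrustes_similarity(model.mean.points, gt.points)
        res = fit(model, profiles, img, init, max_iter=0)
        assert not res.converged
        assert res.iterations == 0
        assert np.allclose(res.landmarks.points, init.apply(model.mean.points))

    def test_residual_history_non_increasing_or_guarded(self, asm_setup,
                                                        phantom_spec,
                                                        small_training):
        model, profiles = asm_setup
        img, gt = self._render_case(phantom_spec, small_training, 3)
        init = procrustes_similarity(model.mean.points, gt.points)
        res = fit(model, profiles, img, init, max_iter=15, m=8)
        h = res.residual_history
        rises = sum(h[i + 1] > h[i] + 1e-12 for i in range(len(h) - 1))
        assert res.converged or rises >= 3
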