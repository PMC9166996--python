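import math

import numpy as np
import pytest
from sklearn.decomposition import FastICA as SkFastICA

from ctdenoise import (
    DimensionError,
    Image,
    NoiseSpec,
    ParameterError,
    PatchConfig,
    degrade,
    fastica_fit,
    ica_denoise,
    ica_separate,
    mse,
    psnr,
    rmse,
)
from ctdenoise.ica import (
    ICAModel,
    center_whiten,
    contrast_eval,
    extract_patches,
    negentropy_objective,
    reconstruct_patches,
    shrink_code,
    PatchGrid,
)


class TestContrast:
    @pytest.mark.parametrize("kind", ["G1", "G2"])
    def test_g_is_odd(self, kind):
        _, g, _ = contrast_eval(np.array([0.0]), kind)
        assert g[0] == 0.0
        _, gp, _ = contrast_eval(np.array([1.5, -1.5]), kind)
        assert gp[0] == pytest.approx(-gp[1])

    def test_logcosh_anchor(self):
        _, g, _ = contrast_eval(np.array([1.0]), "G1", a1=1.0)
        assert g[0] == pytest.approx(math.tanh(1.0), abs=1e-12)

    @pytest.mark.parametrize("kind,a1,a2", [("G1", 1.0, 1.0), ("G1", 1.7, 1.0), ("G2", 1.0, 1.0), ("G2", 1.0, 2.5)])
    def test_gprime_matches_finite_difference(self, kind, a1, a2):
        u = np.linspace(-3, 3, 100)
        h = 1e-6
        _, g_plus, _ = contrast_eval(u + h, kind, a1, a2)
        _, g_minus, _ = contrast_eval(u - h, kind, a1, a2)
        _, _, gp = contrast_eval(u, kind, a1, a2)
        np.testing.assert_allclose(gp, (g_plus - g_minus) / (2 * h), atol=1e-6)

    def test_g_matches_derivative_of_G(self):
        u = np.linspace(-3, 3, 100)
        h = 1e-6
        for kind in ("G1", "G2"):
            Gp, _, _ = contrast_eval(u + h, kind)
            Gm, _, _ = contrast_eval(u - h, kind)
            _, g, _ = contrast_eval(u, kind)
            np.testing.assert_allclose(g, (Gp - Gm) / (2 * h), atol=1e-6)

    def test_parameter_domains(self):
        with pytest.raises(ParameterError):
            contrast_eval(np.zeros(3), "G1", a1=0.5)
        with pytest.raises(ParameterError):
            contrast_eval(np.zeros(3), "G2", a2=0.0)
        with pytest.raises(ParameterError):
            contrast_eval(np.zeros(3), "G3")


class TestWhitening:
    def test_output_covariance_is_identity(self, rng):
        X = rng.normal(size=(5000, 4)) @ rng.normal(size=(4, 4))
        Z, K, mean = center_whiten(X)
        cov = Z.T @ Z / len(Z)
        np.testing.assert_allclose(cov, np.eye(Z.shape[1]), atol=1e-8)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)

    def test_1d_variance_four_gives_half(self):
        x = np.array([[-2.0], [2.0], [-2.0], [2.0], [-2.0], [2.0]])
        _, K, _ = center_whiten(x)
        assert K.shape == (1, 1)
        assert abs(K[0, 0]) == pytest.approx(0.5, rel=1e-12)

    def test_rank_deficiency_drops_dimensions(self, rng):
        x = rng.normal(size=(1000, 2))
        X = np.column_stack([x[:, 0], x[:, 1], x[:, 0] + x[:, 1]])  # rank 2
        Z, K, _ = center_whiten(X)
        assert Z.shape[1] == 2

    def test_needs_more_observations_than_dims(self):
        with pytest.raises(DimensionError):
            center_whiten(np.zeros((3, 5)))


def _laplacian_mixture(seed, n=20000):
    rng = np.random.default_rng(seed)
    S = rng.laplace(size=(n, 2))
    return S, S @ np.array([[2.0, 1.0], [1.0, 1.0]]).T


class TestFastICA:
    def test_single_source_recovers_unit_vector(self, rng):
        x = rng.laplace(size=(5000, 1))
        model = fastica_fit(x, n_components=1, seed=0)
        assert abs(model.components[0, 0]) == pytest.approx(1.0, abs=1e-9)
        assert model.converged.all()

    def test_two_laplacian_sources_recovered(self):
        S, X = _laplacian_mixture(seed=0)
        model = fastica_fit(X, n_components=2, seed=0)
        Y = model.transform(X)
        C = np.abs(np.corrcoef(np.hstack([S, Y]).T)[:2, 2:])
        assert max(C[0, 0], C[0, 1]) > 0.95
        assert max(C[1, 0], C[1, 1]) > 0.95

    def test_components_orthonormal(self, rng):
        X = rng.laplace(size=(3000, 5)) @ rng.normal(size=(5, 5))
        model = fastica_fit(X, seed=1)
        W = model.components
        np.testing.assert_allclose(W @ W.T, np.eye(len(W)), atol=1e-8)

    def test_matches_sklearn_oracle(self):
        S, X = _laplacian_mixture(seed=3)
        ours = fastica_fit(X, n_components=2, seed=3).transform(X)
        sk = SkFastICA(n_components=2, random_state=3, whiten="unit-variance").fit_transform(X)
        C = np.abs(np.corrcoef(np.hstack([ours, sk]).T)[:2, 2:])
        # same sources up to sign/permutation/scale
        assert max(C[0, 0], C[0, 1]) > 0.99
        assert max(C[1, 0], C[1, 1]) > 0.99

    def test_gaussian_mixture_has_flat_objective(self, rng):
        # Gaussian data are rotationally unidentifiable: whatever directions
        # the iteration settles on carry no real structure — their negentropy
        # stays at the Gaussian floor, far below any genuine source's
        X = rng.standard_normal((20000, 2)) @ np.array([[2.0, 1.0], [1.0, 1.0]]).T
        model = fastica_fit(X, n_components=2, seed=0)
        Y = model.transform(X)
        for j in range(2):
            assert negentropy_objective(Y[:, j]) < 1e-3
        S, Xl = _laplacian_mixture(seed=0)
        Yl = fastica_fit(Xl, n_components=2, seed=0).transform(Xl)
        assert min(negentropy_objective(Yl[:, j]) for j in range(2)) > 1e-3

    def test_n_components_validation(self, rng):
        X = rng.laplace(size=(100, 3))
        with pytest.raises(ParameterError):
            fastica_fit(X, n_components=4)

    def test_model_json_round_trip(self, tmp_path, rng):
        X = rng.laplace(size=(2000, 3))
        model = fastica_fit(X, seed=5)
        model.to_json(tmp_path / "model.json")
        back = ICAModel.from_json(tmp_path / "model.json")
        np.testing.assert_array_equal(back.components, model.components)
        np.testing.assert_array_equal(back.whitening, model.whitening)
        np.testing.assert_array_equal(back.converged, model.converged)


class TestNegentropy:
    def test_gaussian_near_zero(self):
        y = np.random.default_rng(0).standard_normal(100_000)
        assert negentropy_objective(y) < 1e-3

    def test_laplacian_exceeds_gaussian_seed_paired(self):
        rng = np.random.default_rng(7)
        g = rng.standard_normal(50_000)
        l = rng.laplace(size=50_000) / math.sqrt(2)
        assert negentropy_objective(l) > negentropy_objective(g)

    def test_p_is_monotone_rescaling(self, rng):
        Z = rng.laplace(size=(5000, 3)) @ np.linalg.qr(rng.normal(size=(3, 3)))[0]
        dirs = [v / np.linalg.norm(v) for v in rng.normal(size=(6, 3))]
        obj1 = [negentropy_objective(Z @ d, p=1.0) for d in dirs]
        obj2 = [negentropy_objective(Z @ d, p=2.0) for d in dirs]
        assert np.argsort(obj1).tolist() == np.argsort(obj2).tolist()

    def test_extracted_components_beat_random_directions(self, small_phantom, rng):
        noisy = degrade(small_phantom, NoiseSpec("additive_gaussian", 0.0, 15.0, seed=2))
        patches, _, _ = extract_patches(noisy, PatchConfig(patch_size=8, stride=8))
        model = fastica_fit(patches, n_components=8, seed=0)
        Z, _, _ = center_whiten(patches)
        best = max(negentropy_objective(Z @ w) for w in model.components)
        randoms = []
        for _ in range(20):
            v = rng.normal(size=Z.shape[1])
            randoms.append(negentropy_objective(Z @ (v / np.linalg.norm(v))))
        assert best >= np.median(randoms)


class TestPatches:
    def test_whole_image_patch(self, rng):
        img = Image(rng.uniform(0, 255, (8, 8)))
        patches, means, grid = extract_patches(img, PatchConfig(8, 8, remove_dc=False))
        assert patches.shape == (1, 64)
        np.testing.assert_array_equal(patches[0].reshape(8, 8), img.pixels)

    def test_exact_tiling(self, rng):
        img = Image(rng.uniform(0, 255, (16, 16)))
        patches, _, grid = extract_patches(img, PatchConfig(8, 8))
        assert patches.shape == (4, 64)
        assert grid.origins_r == (0, 8) and grid.origins_c == (0, 8)

    def test_clamped_final_origins(self, rng):
        img = Image(rng.uniform(0, 255, (10, 10)))
        patches, _, grid = extract_patches(img, PatchConfig(8, 4))
        assert grid.origins_r == (0, 2) and grid.origins_c == (0, 2)
        assert patches.shape == (4, 64)

    @pytest.mark.parametrize("cfg", [PatchConfig(8, 4), PatchConfig(8, 3, remove_dc=False), PatchConfig(5, 5)])
    def test_lossless_round_trip(self, small_phantom, cfg):
        patches, means, grid = extract_patches(small_phantom, cfg)
        rec = reconstruct_patches(patches, means, grid)
        np.testing.assert_allclose(rec.pixels, small_phantom.pixels, atol=1e-12)

    def test_overlap_disagreement_averaged(self):
        grid = PatchGrid(origins_r=(0,), origins_c=(0, 1), patch_size=2, image_shape=(2, 3), gray_range=255.0)
        patches = np.array([[1.0, 3.0, 1.0, 3.0], [1.0, 4.0, 1.0, 4.0]])
        rec = reconstruct_patches(patches, np.zeros(2), grid)
        # column 1 covered by both patches: (3 + 1) / 2 = 2
        np.testing.assert_array_equal(rec.pixels[:, 1], [2.0, 2.0])

    def test_patch_larger_than_image(self):
        with pytest.raises(DimensionError):
            extract_patches(Image(np.zeros((4, 4))), PatchConfig(8, 4))

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            PatchConfig(patch_size=1)
        with pytest.raises(ParameterError):
            PatchConfig(patch_size=8, stride=9)

    def test_inconsistent_geometry(self, rng):
        img = Image(rng.uniform(0, 255, (16, 16)))
        patches, means, grid = extract_patches(img, PatchConfig(8, 8))
        with pytest.raises(DimensionError):
            reconstruct_patches(patches[:2], means[:2], grid)


class TestShrinkCode:
    def test_zero_sigma_identity(self, rng):
        c = rng.normal(size=100)
        np.testing.assert_array_equal(shrink_code(c, 0.0, 1.0), c)

    def test_kill_zone_and_piecewise_values(self):
        assert shrink_code(np.array([1.5]), 1.0, 0.5)[0] == 0.0  # |c| < t = 2
        out = shrink_code(np.array([5.0, -5.0]), math.sqrt(2.0), 1.0)  # t = 2
        np.testing.assert_allclose(out, [3.0, -3.0])

    def test_zero_scale_kills_component(self):
        np.testing.assert_array_equal(shrink_code(np.array([4.0, -4.0]), 1.0, 0.0), [0.0, 0.0])


class TestIcaDenoise:
    def test_sigma_zero_is_near_identity(self, small_phantom):
        out = ica_denoise(small_phantom, sigma=0.0, seed=0)
        assert rmse(small_phantom, out) < 1.0

    def test_deterministic_given_seed(self, small_phantom):
        noisy = degrade(small_phantom, NoiseSpec("additive_gaussian", 0.0, 20.0, seed=8))
        a = ica_denoise(noisy, sigma=20.0, seed=3)
        b = ica_denoise(noisy, sigma=20.0, seed=3)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_improves_psnr_by_two_db(self, small_phantom):
        noisy = degrade(small_phantom, NoiseSpec("additive_gaussian", 0.0, 20.0, seed=9))
        out = ica_denoise(noisy, sigma=20.0, seed=0)
        assert psnr(small_phantom, out) >= psnr(small_phantom, noisy) + 2.0

    def test_never_degrades_mse_when_sigma_known(self, small_phantom):
        noisy = degrade(small_phantom, NoiseSpec("additive_gaussian", 0.0, 10.0, seed=10))
        out = ica_denoise(noisy, sigma=10.0, seed=0)
        assert mse(small_phantom, out) <= 1.01 * mse(small_phantom, noisy)

    def test_auto_sigma_runs_and_helps(self, small_phantom):
        noisy = degrade(small_phantom, NoiseSpec("additive_gaussian", 0.0, 20.0, seed=11))
        out = ica_denoise(noisy, sigma="auto", seed=0)
        assert psnr(small_phantom, out) > psnr(small_phantom, noisy)

    def test_model_reuse(self, small_phantom):
        noisy = degrade(small_phantom, NoiseSpec("additive_gaussian", 0.0, 20.0, seed=12))
        patches, _, _ = extract_patches(noisy, PatchConfig())
        model = fastica_fit(patches, seed=0)
        out = ica_denoise(noisy, sigma=20.0, model=model)
        assert psnr(small_phantom, out) > psnr(small_phantom, noisy)


class TestSeparation:
    def test_unmixes_signal_from_noise_observations(self, small_phantom, rng):
        noise_img = Image(rng.normal(0, 30, small_phantom.shape) + 100.0, 255.0)
        m1 = Image(0.8 * small_phantom.pixels + 0.2 * noise_img.pixels, 255.0)
        m2 = Image(0.3 * small_phantom.pixels + 0.7 * noise_img.pixels, 255.0)
        sources, model = ica_separate([m1, m2], seed=0)
        corr = [
            abs(np.corrcoef(s.pixels.ravel(), small_phantom.pixels.ravel())[0, 1])
            for s in sources
        ]
        assert max(corr) > 0.9

    def test_needs_two_images(self, small_phantom):
        with pytest.raises(ParameterError):
            ica_separate([small_phantom])
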