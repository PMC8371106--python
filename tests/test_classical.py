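"""Classical pipeline: grayscale, bilateral, GLCM, HOG, merging, SVM."""

import numpy as np
import pytest

from pomgrade.classical import (ClassicalConfig, ClassicalModel, GLCMatrix,
                                bilateral_filter, extract_features,
                                gamma_compress, glcm, glcm_feature_block,
                                glcm_features, gradients, hog,
                                merge_features, quantize_gray,
                                to_grayscale_weighted, train_svm)
from pomgrade.grades import MIDDLE, POOR, PREMIUM
from pomgrade.synthgen import generate_apple_image, high_contrast_config

from conftest import make_image


def checkerboard(n=2, h=8, w=8):
    """Gray image alternating 0 / 255 horizontally and vertically."""
    yy, xx = np.mgrid[0:h, 0:w]
    return (((yy + xx) % 2) * 255).astype(np.uint8)


class TestGrayscale:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 255, 255), 255),   # weights sum to 1
        ((255, 0, 0), 76),        # round(0.299 * 255)
        ((0, 255, 0), 150),       # round(0.587 * 255)
        ((131, 131, 131), 131),   # achromatic input is unchanged
    ])
    def test_weighted_mean(self, rgb, expected):
        img = np.full((4, 4, 3), rgb, dtype=np.uint8)
        assert (to_grayscale_weighted(img) == expected).all()

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale_weighted(np.zeros((4, 4), dtype=np.uint8))


def brute_force_bilateral(gray, win, sigma_color, sigma_space):
    """Direct double loop over the window (replicated borders): the
    definitional oracle."""
    g = gray.astype(np.float64)
    h, w = g.shape
    r = win // 2
    gp = np.pad(g, r, mode="edge")
    out = np.empty_like(g)
    for i in range(h):
        for j in range(w):
            num = den = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    v = gp[i + r + di, j + r + dj]
                    ws = np.exp(-(di * di + dj * dj) / (2 * sigma_space ** 2))
                    wc = np.exp(-((v - g[i, j]) ** 2)
                                / (2 * sigma_color ** 2))
                    num += ws * wc * v
                    den += ws * wc
            out[i, j] = num / den
    return out


class TestBilateral:
    def test_constant_image_unchanged(self):
        g = np.full((16, 16), 90, dtype=np.uint8)
        np.testing.assert_array_equal(bilateral_filter(g, 9, 75, 75), g)

    def test_matches_brute_force_on_step_image(self):
        g = np.full((16, 16), 60, dtype=np.uint8)
        g[:, 8:] = 180
        rng = np.random.default_rng(0)
        g = np.clip(g + rng.integers(-5, 6, g.shape), 0, 255).astype(np.uint8)
        got = bilateral_filter(g, 5, 40.0, 2.0).astype(np.float64)
        ref = brute_force_bilateral(g, 5, 40.0, 2.0)
        assert np.abs(got - ref).max() <= 1.0  # quantization + LUT binning

    def test_step_edge_position_preserved_flat_variance_reduced(self):
        g = np.full((32, 32), 50, dtype=np.uint8)
        g[:, 16:] = 200
        rng = np.random.default_rng(1)
        noisy = np.clip(g + rng.integers(-8, 9, g.shape), 0, 255).astype(np.uint8)
        out = bilateral_filter(noisy, 7, 50.0, 3.0)
        grad_cols_in = np.abs(np.diff(noisy.astype(int), axis=1)).sum(axis=0)
        grad_cols_out = np.abs(np.diff(out.astype(int), axis=1)).sum(axis=0)
        assert grad_cols_out.argmax() == grad_cols_in.argmax() == 15
        assert out[:, :12].std() < noisy[:, :12].std()

    def test_impulse_amplitude_strictly_reduced(self):
        g = np.full((15, 15), 100, dtype=np.uint8)
        g[7, 7] = 160
        out = bilateral_filter(g, 7, 75.0, 3.0)
        assert out[7, 7] < 160

    def test_output_within_input_range(self, apple_image):
        gray = to_grayscale_weighted(apple_image.pixels)
        out = bilateral_filter(gray, 9, 75, 75)
        assert out.min() >= gray.min() and out.max() <= gray.max()

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            bilateral_filter(np.zeros((8, 8), dtype=np.uint8), 9, -1.0, 75)


def brute_force_glcm(q, distance, angle_deg, n_levels):
    """Enumerate co-occurring pairs at offset (round(d sin a), round(d cos a)),
    counted in both directions, normalized."""
    dr = int(round(distance * np.sin(np.deg2rad(angle_deg))))
    dc = int(round(distance * np.cos(np.deg2rad(angle_deg))))
    h, w = q.shape
    m = np.zeros((n_levels, n_levels))
    for i in range(h):
        for j in range(w):
            ii, jj = i + dr, j + dc
            if 0 <= ii < h and 0 <= jj < w:
                m[q[i, j], q[ii, jj]] += 1
                m[q[ii, jj], q[i, j]] += 1
    return m / m.sum()


class TestGLCM:
    def test_constant_image_single_diagonal_entry(self):
        g = np.full((8, 8), 100, dtype=np.uint8)
        m = glcm(g, 1, 0.0, n_levels=8)
        level = quantize_gray(g, 8)[0, 0]
        assert m.probs[level, level] == 1.0
        assert m.probs.sum() == pytest.approx(1.0)

    def test_checkerboard_off_diagonal_half_half(self):
        m = glcm(checkerboard(h=2, w=2), 1, 0.0, n_levels=2)
        assert m.probs[0, 1] == pytest.approx(0.5)
        assert m.probs[1, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("angle", [0.0, 45.0, 90.0, 135.0])
    def test_matches_brute_force_enumeration(self, rng, angle):
        g = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        m = glcm(g, 1, angle, n_levels=8)
        ref = brute_force_glcm(quantize_gray(g, 8), 1, angle, 8)
        np.testing.assert_allclose(m.probs, ref, atol=1e-12)

    def test_offset_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((4, 4), dtype=np.uint8), distance=10)


class TestGLCMFeatures:
    def test_constant_matrix_closed_form(self):
        g = np.full((8, 8), 100, dtype=np.uint8)
        f = glcm_features(glcm(g, 1, 0.0, 8))
        assert f.asm == pytest.approx(1.0)
        assert f.ent == pytest.approx(0.0)
        assert f.con == pytest.approx(0.0)
        assert f.cor == 0.0  # degenerate marginals convention

    def test_checkerboard_closed_form(self):
        f = glcm_features(glcm(checkerboard(), 1, 0.0, 2))
        assert f.asm == pytest.approx(0.5)
        assert f.ent == pytest.approx(np.log(2))
        assert f.con == pytest.approx(1.0)
        assert f.cor == pytest.approx(-1.0)

    def test_matches_brute_force_double_loop(self, rng):
        g = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        m = glcm(g, 1, 45.0, 16)
        f = glcm_features(m)
        p = m.probs
        asm = ent = con = 0.0
        mu_i = mu_j = 0.0
        for i in range(16):
            for j in range(16):
                asm += p[i, j] ** 2
                if p[i, j] > 0:
                    ent -= p[i, j] * np.log(p[i, j])
                con += (i - j) ** 2 * p[i, j]
                mu_i += i * p[i, j]
                mu_j += j * p[i, j]
        cov = si = sj = 0.0
        for i in range(16):
            for j in range(16):
                cov += (i - mu_i) * (j - mu_j) * p[i, j]
                si += (i - mu_i) ** 2 * p[i, j]
                sj += (j - mu_j) ** 2 * p[i, j]
        assert f.asm == pytest.approx(asm)
        assert f.ent == pytest.approx(ent)
        assert f.con == pytest.approx(con)
        assert f.cor == pytest.approx(cov / np.sqrt(si * sj))

    def test_unnormalized_matrix_rejected(self):
        bad = GLCMatrix(np.ones((4, 4)), 1, 0.0, 4)
        with pytest.raises(ValueError):
            glcm_features(bad)

    def test_invariants_on_random_images(self, rng):
        for _ in range(5):
            g = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            f = glcm_features(glcm(g, 1, 0.0, 8))
            assert 0.0 < f.asm <= 1.0
            assert f.ent >= 0.0 and f.con >= 0.0
            assert -1.0 <= f.cor <= 1.0


class TestGLCMFeatureBlock:
    def test_constant_image_zero_variances(self):
        g = np.full((16, 16), 200, dtype=np.uint8)
        block = glcm_feature_block(g)
        np.testing.assert_allclose(block[:4], [1.0, 0.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(block[4:], 0.0, atol=1e-12)

    def test_90_degree_symmetric_image_has_zero_variance_over_0_90(self):
        g = checkerboard(h=8, w=8)  # invariant under 90° rotation
        block = glcm_feature_block(g, angles=(0.0, 90.0), n_levels=2)
        np.testing.assert_allclose(block[4:], 0.0, atol=1e-12)

    def test_pooling_matches_per_angle_recomputation(self, rng):
        g = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        angles = (0.0, 45.0, 90.0, 135.0)
        block = glcm_feature_block(g, (1,), angles, 16)
        per = np.array([glcm_features(glcm(g, 1, a, 16)).as_array()
                        for a in angles])
        np.testing.assert_allclose(block[:4], per.mean(axis=0))
        np.testing.assert_allclose(block[4:], per.var(axis=0))


class TestGammaCompress:
    def test_endpoints_fixed(self):
        arr = np.array([0, 255], dtype=np.uint8)
        np.testing.assert_array_equal(gamma_compress(arr), arr)

    def test_mid_value(self):
        assert gamma_compress(np.array([64], dtype=np.uint8))[0] == 128

    def test_monotone_nondecreasing(self):
        ramp = np.arange(256, dtype=np.uint8)
        out = gamma_compress(ramp)
        assert (np.diff(out.astype(int)) >= 0).all()


class TestGradients:
    def test_constant_image_all_zero(self):
        gx, gy, mag, _ = gradients(np.full((8, 8), 7, dtype=np.uint8))
        assert not gx.any() and not gy.any() and not mag.any()

    def test_horizontal_ramp(self):
        g = np.tile(np.arange(0, 40, 5, dtype=np.uint8), (8, 1))
        gx, gy, _, ori = gradients(g)
        assert (gx[:, 1:-1] == 10).all()  # centred difference spans 2 px
        assert not gy.any()
        assert (ori[:, 1:-1] == 0.0).all()

    def test_vertical_step_concentrates_magnitude_on_edge_columns(self):
        g = np.zeros((8, 8), dtype=np.uint8)
        g[:, 4:] = 200
        _, _, mag, _ = gradients(g)
        assert set(np.nonzero(mag.sum(axis=0))[0]) == {3, 4}


class TestHOG:
    def test_constant_image_zero_descriptor(self):
        d = hog(np.full((64, 64), 120, dtype=np.uint8))
        assert not d.vector.any()

    def test_descriptor_length_by_block_enumeration(self):
        d = hog(np.zeros((64, 64), dtype=np.uint8), cell_px=8,
                cells_per_block=4, n_bins=9, block_stride_cells=1)
        # 8x8 cells, (8-4+1)^2 = 25 block positions, 16 cells x 9 bins each
        assert d.n_blocks == (5, 5)
        assert len(d) == 25 * 16 * 9 == 3600

    def test_block_subvectors_have_norm_at_most_one(self, rng):
        g = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        d = hog(g)
        block_len = d.cells_per_block ** 2 * d.n_bins
        blocks = d.vector.reshape(-1, block_len)
        assert (np.linalg.norm(blocks, axis=1) <= 1.0 + 1e-6).all()

    def test_invariant_to_constant_brightness_shift(self, rng):
        g = rng.integers(40, 120, size=(64, 64)).astype(np.uint8)
        d1 = hog(g, gamma=False)
        d2 = hog((g + 60).astype(np.uint8), gamma=False)
        np.testing.assert_allclose(d1.vector, d2.vector, atol=1e-12)

    def test_image_smaller_than_block_rejected(self):
        with pytest.raises(ValueError):
            hog(np.zeros((16, 16), dtype=np.uint8), cell_px=8,
                cells_per_block=4)


class TestMergeAndScale:
    def test_lengths_add(self, rng):
        g = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        block = glcm_feature_block(g)
        d = hog(g)
        merged = merge_features(block, d)
        assert merged.shape == (8 + len(d),)
        np.testing.assert_array_equal(merged[:8], block)

    def test_validation_standardized_with_training_statistics(self, small_cfg):
        """A validation set shifted away from the training distribution must
        keep a nonzero mean after scaling — proof the training statistics,
        not its own, were applied."""
        cfg = high_contrast_config((64, 64), seed=3)
        tr = [generate_apple_image(g, cfg, i)
              for i in range(10) for g in (PREMIUM, POOR)]
        model = ClassicalModel(ClassicalConfig(bilateral_diameter=5)).fit(tr)
        x_tr = model.features(tr)
        np.testing.assert_allclose(x_tr.mean(axis=0), 0.0, atol=1e-9)
        shifted_cfg = high_contrast_config((64, 64), seed=3)
        shifted_cfg.defect_contrast = {0: 0.9, 1: 0.92, 2: 0.95}
        va = [generate_apple_image(g, shifted_cfg, 100 + i)
              for i in range(5) for g in (PREMIUM, POOR)]
        x_va = model.features(va)
        assert np.abs(x_va.mean(axis=0)).max() > 0.5


class TestSVM:
    def test_separated_clouds_reach_perfect_training_accuracy(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (20, 4)),
                       rng.normal(5, 0.1, (20, 4))])
        y = np.repeat([0, 2], 20)
        svc = train_svm(x, y)
        assert (svc.predict(x) == y).all()

    def test_prediction_invariant_to_duplicating_training_points(self, rng):
        x = np.vstack([rng.normal(0, 0.5, (15, 3)),
                       rng.normal(3, 0.5, (15, 3)),
                       rng.normal(-3, 0.5, (15, 3))])
        y = np.repeat([0, 1, 2], 15)
        grid = rng.normal(0, 3, (40, 3))
        p1 = train_svm(x, y).predict(grid)
        p2 = train_svm(np.vstack([x, x]), np.hstack([y, y])).predict(grid)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_svm(rng.normal(size=(10, 3)), np.zeros(10))


class TestEndToEnd:
    def test_feature_extraction_is_bit_stable(self):
        cfg = high_contrast_config((64, 64), seed=8)
        samples = [generate_apple_image(g, cfg, i)
                   for i, g in enumerate((PREMIUM, MIDDLE, POOR, MIDDLE))]
        cc = ClassicalConfig(bilateral_diameter=5)
        f1 = np.stack([extract_features(s, cc) for s in samples])
        f2 = np.stack([extract_features(s, cc) for s in samples])
        np.testing.assert_array_equal(f1, f2)

    def test_model_save_load_round_trip(self, tmp_path):
        cfg = high_contrast_config((64, 64), seed=2)
        samples = [generate_apple_image(g, cfg, i)
                   for i in range(6) for g in (PREMIUM, MIDDLE, POOR)]
        model = ClassicalModel(ClassicalConfig(bilateral_diameter=5)).fit(samples)
        path = str(tmp_path / "model.pkl")
        model.save(path)
        loaded = ClassicalModel.load(path)
        np.testing.assert_array_equal(loaded.predict(samples),
                                      model.predict(samples))
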