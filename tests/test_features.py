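import numpy as np
import pytest

from cvigrade.features import (LAYOUT, assemble, color_stats,
                               compute_feature_matrix, context_features,
                               dense_sift_stats, edge_histogram,
                               glcm_stats, gradient_mean, lbp_histogram,
                               patch_summary, rgb_to_ycbcr)
from cvigrade.grid import divide, grid_spec_of
from cvigrade.image import LegImage, ValidationError


@pytest.fixture
def window(rng):
    return rng.uniform(0, 255, size=(25, 25))


class TestLBP:
    def test_constant_patch_single_bin(self):
        h = lbp_histogram(np.full((15, 15), 77.0))
        assert h.max() == 1.0 and (h > 0).sum() == 1

    def test_sums_to_one(self, window):
        assert lbp_histogram(window).sum() == pytest.approx(1.0, abs=1e-12)

    def test_gray_shift_invariance(self, window):
        w = np.floor(window)
        np.testing.assert_allclose(lbp_histogram(w), lbp_histogram(w + 40.0))

    def test_too_small_window_rejected(self):
        with pytest.raises(ValidationError):
            lbp_histogram(np.zeros((2, 2)))


class TestEHD:
    def test_vertical_step_edge(self):
        # alternating dark/bright columns: every 2x2 sub-block is a vertical edge
        w = np.zeros((10, 10))
        w[:, 1::2] = 200.0
        h = edge_histogram(w)
        assert h[0] == 1.0  # all mass on the vertical bin
        # hand-check of the filter response on one sub-block (a,b,c,d)=(0,200,0,200):
        # |a-b+c-d| = 400 >= threshold, dominating all other responses

    def test_horizontal_step_edge(self):
        w = np.zeros((10, 10))
        w[1::2, :] = 200.0
        assert edge_histogram(w)[1] == 1.0

    def test_constant_patch_all_zero(self):
        np.testing.assert_array_equal(
            edge_histogram(np.full((8, 8), 100.0)), np.zeros(5))

    def test_normalization_when_nonzero(self, window):
        h = edge_histogram(window)
        assert h.sum() == pytest.approx(1.0) or not h.any()

    def test_sub_threshold_blocks_ignored(self):
        w = np.zeros((6, 6))
        w[:, 3:] = 2.0  # max response 8 < threshold 11
        np.testing.assert_array_equal(edge_histogram(w), np.zeros(5))


class TestGLCM:
    def test_constant_patch_conventions(self):
        contrast, corr, energy, homog = glcm_stats(np.full((10, 10), 42.0))
        assert (contrast, corr, energy, homog) == (0.0, 0.0, 1.0, 1.0)

    def test_checkerboard_contrast_oracle(self):
        # two quantized levels 0 and 5 (pixel values 0 and 80):
        # horizontally adjacent pairs always differ -> contrast = 25 for (0,1)
        w = np.indices((8, 8)).sum(axis=0) % 2 * 80.0
        levels_diff2 = 5 ** 2
        # oracle by direct enumeration for each offset
        q = (w / 16).astype(int)
        expected = []
        for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
            a = q[max(0, -dy):q.shape[0] - max(0, dy),
                  max(0, -dx):q.shape[1] - max(0, dx)]
            b = q[max(0, dy):, max(0, dx):][:a.shape[0], :a.shape[1]]
            expected.append(np.mean((a - b) ** 2 * 1.0))
        contrast = glcm_stats(w)[0]
        assert contrast == pytest.approx(np.mean(expected))
        assert expected[0] == levels_diff2  # horizontal neighbors always differ

    def test_energy_in_unit_interval(self, window):
        energy = glcm_stats(window)[2]
        assert 0 < energy <= 1


class TestDenseSift:
    def test_constant_patch_zero(self):
        v = dense_sift_stats(np.full((25, 25), 99.0))
        np.testing.assert_array_equal(v, np.zeros(256))

    def test_variance_block_nonnegative(self, rng):
        v = dense_sift_stats(rng.uniform(0, 255, size=(50, 50)))
        assert (v[128:] >= -1e-15).all()

    def test_single_site_zero_variance(self, rng):
        # a 15x15 patch fits exactly one descriptor site
        v = dense_sift_stats(rng.uniform(0, 255, size=(15, 15)))
        np.testing.assert_allclose(v[128:], 0.0)

    def test_descriptor_norm_bounded(self, rng):
        v = dense_sift_stats(rng.uniform(0, 255, size=(25, 25)))
        mean = v[:128]
        assert np.linalg.norm(mean) <= 1.0 + 1e-9


class TestGradientMean:
    def test_constant_zero(self):
        assert gradient_mean(np.full((10, 10), 5.0)) == 0.0

    def test_unit_ramp(self):
        w = np.tile(np.arange(20.0), (20, 1))
        assert gradient_mean(w) == pytest.approx(1.0)

    def test_shift_invariance(self, window):
        assert gradient_mean(window) == pytest.approx(
            gradient_mean(window + 31.0))


class TestColorStats:
    def test_constant_color(self):
        w = np.zeros((5, 5, 3))
        w[..., 0], w[..., 1], w[..., 2] = 200.0, 100.0, 50.0
        v = color_stats(w)
        rgb = v[:9].reshape(3, 3)
        np.testing.assert_allclose(rgb[:, 0], [200, 100, 50])  # means
        np.testing.assert_allclose(rgb[:, 1], [200, 100, 50])  # medians
        np.testing.assert_allclose(rgb[:, 2], 0.0)             # variances

    def test_grayscale_neutral_chroma(self, rng):
        g = rng.uniform(0, 255, size=(8, 8))
        w = np.stack([g, g, g], axis=-1)
        v = color_stats(w).reshape(6, 3)
        np.testing.assert_allclose(v[4, :2], 128.0, atol=1e-9)  # Cb mean/median
        np.testing.assert_allclose(v[5, :2], 128.0, atol=1e-9)  # Cr mean/median

    def test_variances_nonnegative(self, rng):
        v = color_stats(rng.uniform(0, 255, size=(6, 6, 3)))
        assert (v.reshape(6, 3)[:, 2] >= 0).all()

    def test_ycbcr_identity_bt601(self):
        w = np.array([[[255.0, 0.0, 0.0]]])
        ycc = rgb_to_ycbcr(w)[0, 0]
        np.testing.assert_allclose(ycc, [76.245, 84.972, 255.5], atol=0.01)


class TestContextAndAssemble:
    def _uniform_image(self):
        return LegImage(np.full((700, 250, 3), 120.0),
                        np.ones((700, 250), dtype=bool))

    def test_interior_patch_in_constant_image(self):
        img = self._uniform_image()
        patches = divide(img, 50)
        summaries = np.array([patch_summary(p.window(img.pixels))
                              for p in patches])
        interior = next(p for p in patches
                        if 0 < p.row_index < 13 and 0 < p.col_index < 4)
        ctx = context_features(interior, patches, summaries)
        k = interior.row_index * 5 + interior.col_index
        np.testing.assert_allclose(ctx, summaries[k])

    def test_corner_patch_uses_two_neighbors(self):
        img = self._uniform_image()
        patches = divide(img, 50)
        summaries = np.arange(len(patches) * 7, dtype=float).reshape(-1, 7)
        corner = patches[0]
        ctx = context_features(corner, patches, summaries)
        np.testing.assert_allclose(ctx, (summaries[1] + summaries[5]) / 2)

    def test_no_included_neighbor_gives_zeros(self):
        img = self._uniform_image()
        patches = divide(img, 50)
        summaries = np.ones((len(patches), 7))
        included = np.zeros(len(patches), dtype=bool)
        included[0] = True
        ctx = context_features(patches[0], patches, summaries, included)
        np.testing.assert_array_equal(ctx, np.zeros(7))

    def test_assemble_layout(self, rng):
        img = self._uniform_image()
        patches = divide(img, 50)
        spec = grid_spec_of(patches)
        offsets = LAYOUT.offsets()
        assert offsets["patch_index"][1] == LAYOUT.length
        blocks = {
            "lbp": rng.dirichlet(np.ones(59)),
            "ehd": rng.dirichlet(np.ones(5)),
            "glcm": rng.random(4),
            "sift_stats": rng.random(256),
            "grad_mean": 1.0,
            "color_stats": rng.random(18),
            "context": rng.random(7),
        }
        v0 = assemble(patches[0], blocks, spec)
        assert v0.shape == (LAYOUT.length,)
        np.testing.assert_array_equal(v0[LAYOUT.slice("patch_index")], [0, 0])
        v = assemble(patches[-1], blocks, spec)
        np.testing.assert_allclose(
            v[LAYOUT.slice("patch_index")], [13 / 14, 4 / 5])
        missing = dict(blocks)
        del missing["glcm"]
        with pytest.raises(ValidationError):
            assemble(patches[0], missing, spec)


class TestFeatureMatrix:
    def test_deterministic_and_finite(self, synth_image):
        patches = divide(synth_image.image, 50)
        a = compute_feature_matrix(synth_image.image, patches)
        b = compute_feature_matrix(synth_image.image, patches)
        np.testing.assert_array_equal(a, b)
        assert np.isfinite(a).all()
        assert a.shape == (70, LAYOUT.length)

    def test_histogram_blocks_normalized_or_zero(self, synth_image):
        patches = divide(synth_image.image, 50)
        m = compute_feature_matrix(synth_image.image, patches)
        lbp = m[:, LAYOUT.slice("lbp")]
        np.testing.assert_allclose(lbp.sum(axis=1), 1.0, atol=1e-9)
        ehd = m[:, LAYOUT.slice("ehd")]
        sums = ehd.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))
        assert (lbp >= 0).all() and (ehd >= 0).all()
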