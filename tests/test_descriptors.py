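"""Five standard descriptors: frozen dims, degenerate cases, brute-force oracles."""

import numpy as np
import pytest

from pupaevision.descriptors import (
    COLOR_DIM,
    GLCM_DIM,
    GLCM_OFFSETS,
    HOG_DIM,
    HU_DIM,
    LBP_DIM,
    LBP_NEIGHBOR_OFFSETS,
    DescriptorConfig,
    _quantize,
    _uniform_lut,
    compute_color_hist,
    compute_eqlbp,
    compute_glcm,
    compute_hog,
    compute_hu,
    glcm_matrix,
    glcm_stats,
    lbp_codes,
)
from pupaevision.preprocess import CropResult, PupaContour


def make_crop(rgb, mask):
    if mask.any():
        rr, cc = np.nonzero(mask)
        pts = np.array(
            [[rr.min(), cc.min()], [rr.min(), cc.max()],
             [rr.max(), cc.max()], [rr.max(), cc.min()]], dtype=float
        )
    else:  # placeholder contour for degenerate-mask tests
        pts = np.array([[0.0, 0.0], [0.0, 5.0], [5.0, 5.0], [5.0, 0.0]])
    return CropResult(rgb, mask, PupaContour(pts), (0, 0))


@pytest.fixture
def textured_crop():
    rng = np.random.default_rng(3)
    rgb = np.full((320, 320, 3), 235, np.uint8)
    mask = np.zeros((320, 320), bool)
    mask[80:240, 60:260] = True
    body = rng.integers(40, 160, size=(160, 200, 3))
    rgb[80:240, 60:260] = body
    return make_crop(rgb, mask)


@pytest.fixture
def constant_crop():
    rgb = np.full((320, 320, 3), 128, np.uint8)
    mask = np.zeros((320, 320), bool)
    mask[100:220, 100:220] = True
    return make_crop(rgb, mask)


class TestDims:
    def test_all_output_dimensions_frozen(self, pupa_crop):
        assert compute_hog(pupa_crop).shape == (HOG_DIM,)
        assert compute_hu(pupa_crop.crop_mask).shape == (HU_DIM,)
        assert compute_eqlbp(pupa_crop).shape == (LBP_DIM,)
        assert compute_glcm(pupa_crop).shape == (GLCM_DIM,)
        assert compute_color_hist(pupa_crop).shape == (COLOR_DIM,)

    def test_descriptors_deterministic(self, pupa_crop):
        for fn in (compute_hog, compute_eqlbp, compute_glcm, compute_color_hist):
            assert np.array_equal(fn(pupa_crop), fn(pupa_crop))


class TestHog:
    def test_constant_crop_all_zero(self, constant_crop):
        assert not compute_hog(constant_crop).any()

    def test_orientation_sensitive(self, textured_crop):
        rgb = np.ascontiguousarray(np.rot90(textured_crop.crop_rgb))
        mask = np.ascontiguousarray(np.rot90(textured_crop.crop_mask))
        rotated = make_crop(rgb, mask)
        assert not np.allclose(compute_hog(textured_crop), compute_hog(rotated))


class TestHu:
    def blob(self):
        rr, cc = np.mgrid[0:300, 0:300]
        # asymmetric blob: offset ellipse plus a lobe
        m = (((rr - 150) / 60.0) ** 2 + ((cc - 130) / 90.0) ** 2 <= 1) | (
            ((rr - 110) / 30.0) ** 2 + ((cc - 200) / 25.0) ** 2 <= 1
        )
        return m

    def test_similarity_invariance_within_1pct(self):
        from skimage.transform import rescale, rotate

        m = self.blob()
        h0 = compute_hu(m)
        moved = rotate(
            np.pad(m, 100).astype(float), 37, resize=False, order=0
        ) > 0.5
        scaled = rescale(moved.astype(float), 1.6, order=0) > 0.5
        h1 = compute_hu(scaled)
        assert np.abs((h1 - h0) / h0).max() < 0.01

    def test_mirror_flips_seventh_moment_sign(self):
        m = self.blob()
        h = compute_hu(m)
        hm = compute_hu(m[:, ::-1])
        assert np.abs((hm[:6] - h[:6]) / h[:6]).max() < 0.01
        assert np.sign(hm[6]) == -np.sign(h[6])
        assert hm[6] == pytest.approx(-h[6], rel=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_hu(np.zeros((10, 10), bool))


class TestEqLbp:
    def test_histogram_normalized(self, textured_crop):
        h = compute_eqlbp(textured_crop)
        assert h.sum() == pytest.approx(1.0, abs=1e-9)
        assert (h >= 0).all()

    def test_constant_region_single_bin(self, constant_crop):
        h = compute_eqlbp(constant_crop)
        assert np.count_nonzero(h) == 1

    def test_tiny_mask_rejected(self, constant_crop):
        small = make_crop(constant_crop.crop_rgb, np.zeros((320, 320), bool))
        small.crop_mask[5, 5] = True
        with pytest.raises(ValueError, match="9 px"):
            compute_eqlbp(small)

    def test_matches_naive_enumeration(self):
        """Histogram equals a per-pixel double-loop oracle on a 32x32 patch."""
        rng = np.random.default_rng(7)
        patch = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        patch[..., 1] = patch[..., 0]
        patch[..., 2] = patch[..., 0]
        mask = np.ones((32, 32), bool)
        gray = patch[..., 0].astype(float) * 0.299 + patch[..., 1] * 0.587 + patch[..., 2] * 0.114

        def transitions(code):
            bits = [(code >> i) & 1 for i in range(8)]
            return sum(bits[i] != bits[(i + 1) % 8] for i in range(8))

        uniform = [c for c in range(256) if transitions(c) <= 2]
        hist = np.zeros(59)
        for r in range(1, 31):
            for c in range(1, 31):
                code = 0
                for bit, (dr, dc) in enumerate(LBP_NEIGHBOR_OFFSETS):
                    if gray[r + dr, c + dc] >= gray[r, c]:
                        code |= 1 << bit
                hist[uniform.index(code) if code in uniform else 58] += 1
        hist /= hist.sum()

        # same patch through the packaged path (mask restricted to interior)
        crop_rgb = np.zeros((320, 320, 3), np.uint8)
        crop_rgb[:32, :32] = patch
        crop_mask = np.zeros((320, 320), bool)
        crop_mask[1:31, 1:31] = True
        got = compute_eqlbp(make_crop(crop_rgb, crop_mask))
        assert np.allclose(got, hist)

    def test_uniform_lut_properties(self):
        lut = _uniform_lut(8)
        assert lut.max() == 58
        assert (np.bincount(lut) >= 1).all()
        assert np.count_nonzero(lut < 58) == 58


class TestGlcm:
    def test_constant_region_degenerate_stats(self, constant_crop):
        g = compute_glcm(constant_crop)
        for a in range(4):
            asm, contrast, entropy, corr, idm = g[5 * a : 5 * a + 5]
            assert asm == pytest.approx(1.0)
            assert contrast == pytest.approx(0.0)
            assert entropy == pytest.approx(0.0, abs=1e-12)
            assert corr == 0.0  # variance guard
            assert idm == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self):
        """Statistics equal brute-force pair counting on an 8x8 patch."""
        rng = np.random.default_rng(11)
        gray = rng.integers(0, 256, (8, 8)).astype(float)
        mask = np.ones((8, 8), bool)
        levels = 64
        q = _quantize(gray, levels)
        for angle, (dr, dc) in GLCM_OFFSETS.items():
            counts = np.zeros((levels, levels))
            for r in range(8):
                for c in range(8):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < 8 and 0 <= c2 < 8:
                        counts[q[r, c], q[r2, c2]] += 1
                        counts[q[r2, c2], q[r, c]] += 1
            ref = counts / counts.sum()
            got = glcm_matrix(q, mask, (dr, dc), levels)
            assert np.allclose(got, ref)
            # statistics against literal formulas
            i, j = np.mgrid[0:levels, 0:levels]
            asm = (ref**2).sum()
            contrast = ((i - j) ** 2 * ref).sum()
            nz = ref > 0
            entropy = -(ref[nz] * np.log2(ref[nz])).sum()
            mu_i, mu_j = (i * ref).sum(), (j * ref).sum()
            si = np.sqrt(((i - mu_i) ** 2 * ref).sum())
            sj = np.sqrt(((j - mu_j) ** 2 * ref).sum())
            corr = ((i * j * ref).sum() - mu_i * mu_j) / (si * sj)
            idm = (ref / (1 + (i - j) ** 2)).sum()
            assert np.allclose(glcm_stats(ref), [asm, contrast, entropy, corr, idm])

    def test_background_pixels_carry_no_signal(self, textured_crop):
        other = textured_crop.crop_rgb.copy()
        other[~textured_crop.crop_mask] = 10  # repaint the background
        repainted = make_crop(other, textured_crop.crop_mask)
        assert np.array_equal(compute_glcm(textured_crop), compute_glcm(repainted))


class TestColorHist:
    def test_blocks_normalized(self, textured_crop):
        h = compute_color_hist(textured_crop)
        for ch in range(3):
            assert h[256 * ch : 256 * (ch + 1)].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_color_single_bin(self, constant_crop):
        h = compute_color_hist(constant_crop)
        for ch in range(3):
            assert np.count_nonzero(h[256 * ch : 256 * (ch + 1)]) == 1

    def test_counts_sum_to_mask_pixels(self, textured_crop):
        n = textured_crop.crop_mask.sum()
        h = compute_color_hist(textured_crop)
        counts = h * n
        assert np.allclose(counts, np.round(counts))
        assert counts[:256].sum() == pytest.approx(n)

    def test_background_pixels_carry_no_signal(self, textured_crop):
        other = textured_crop.crop_rgb.copy()
        other[~textured_crop.crop_mask] = 3
        repainted = make_crop(other, textured_crop.crop_mask)
        assert np.array_equal(
            compute_color_hist(textured_crop), compute_color_hist(repainted)
        )

    def test_empty_mask_rejected(self, constant_crop):
        bad = make_crop(constant_crop.crop_rgb, np.zeros((320, 320), bool))
        with pytest.raises(ValueError, match="empty"):
            compute_color_hist(bad)
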