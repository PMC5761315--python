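import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermgfr import texture
from dermgfr.imaging import SkinImage, ValidationError
from dermgfr.texture import GLCMatrix, compute_glcm, haralick_features, quantize


def naive_glcm(qimg, distance, angles, symmetric, levels=None):
    """Brute-force pair enumeration oracle (independent of the pipeline)."""
    qimg = np.asarray(qimg)
    if levels is None:
        levels = int(qimg.max()) + 1
    counts = np.zeros((levels, levels))
    h, w = qimg.shape
    for angle in angles:
        dr = int(round(np.sin(angle) * distance))
        dc = int(round(np.cos(angle) * distance))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[qimg[r, c], qimg[r2, c2]] += 1
                    if symmetric:
                        counts[qimg[r2, c2], qimg[r, c]] += 1
    return counts / counts.sum()


def naive_features(p):
    """Loop-based evaluation of the five Haralick sums."""
    L = p.shape[0]
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    if L > 1:
        contrast /= (L - 1) ** 2
    energy = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    hom = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    ent = -sum(p[i, j] * np.log2(p[i, j]) for i in range(L) for j in range(L) if p[i, j] > 0)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mi = sum(i * pi[i] for i in range(L))
    mj = sum(j * pj[j] for j in range(L))
    si = np.sqrt(sum((i - mi) ** 2 * pi[i] for i in range(L)))
    sj = np.sqrt(sum((j - mj) ** 2 * pj[j] for j in range(L)))
    corr = (
        sum((i - mi) * (j - mj) * p[i, j] for i in range(L) for j in range(L)) / (si * sj)
        if si > 0 and sj > 0
        else None
    )
    return contrast, corr, energy, hom, ent


class TestQuantize:
    def test_midgrey_to_middle_bin(self):
        q = quantize(SkinImage(np.full((16, 16), 0.5)), levels=8)
        assert np.all(q == 4)

    def test_top_edge_rule(self):
        q = quantize(SkinImage(np.ones((16, 16))), levels=8)
        assert np.all(q == 7)

    def test_binary_image_two_bins(self):
        px = np.zeros((16, 16))
        px[:8] = 1.0
        q = quantize(SkinImage(px), levels=8)
        assert set(np.unique(q)) == {0, 7}

    @pytest.mark.parametrize("levels", [1, 300])
    def test_levels_out_of_range(self, levels):
        with pytest.raises(ValidationError):
            quantize(SkinImage(np.full((16, 16), 0.5)), levels=levels)


class TestComputeGLCM:
    def test_two_by_two_horizontal_pairs(self):
        qimg = np.array([[0, 0], [1, 1]])
        g = compute_glcm(qimg, distance=1, angles=[0.0], symmetric=True, levels=2)
        assert np.allclose(g.p, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_diagonal_entry(self):
        g = compute_glcm(np.zeros((8, 8), dtype=int), angles=[0.0], levels=1)
        assert g.p.shape == (1, 1)
        assert g.p[0, 0] == 1.0

    def test_normalization_sums_to_one(self, rng):
        qimg = rng.integers(0, 4, (16, 16))
        g = compute_glcm(qimg, levels=4)
        assert abs(g.p.sum() - 1.0) < 1e-12

    def test_symmetric_matrix_is_symmetric(self, rng):
        qimg = rng.integers(0, 4, (12, 12))
        g = compute_glcm(qimg, symmetric=True, levels=4)
        assert np.allclose(g.p, g.p.T)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValidationError):
            compute_glcm(np.array([[0]]), distance=1, angles=[0.0], levels=1)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        data=st.data(),
        h=st.integers(3, 8),
        w=st.integers(3, 8),
        levels=st.integers(2, 4),
        symmetric=st.booleans(),
    )
    def test_matches_naive_pair_counter(self, data, h, w, levels, symmetric):
        qimg = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, levels - 1), min_size=w, max_size=w),
                    min_size=h,
                    max_size=h,
                )
            )
        )
        angles = texture.DEFAULT_ANGLES
        g = compute_glcm(qimg, distance=1, angles=angles, symmetric=symmetric, levels=levels)
        expected = naive_glcm(qimg, 1, angles, symmetric, levels=levels)
        assert np.array_equal(g.p, expected)


class TestHaralickFeatures:
    def test_constant_image_degenerate_values(self):
        g = compute_glcm(np.zeros((8, 8), dtype=int), angles=[0.0], levels=2)
        with pytest.warns(UserWarning, match="correlation undefined"):
            f = haralick_features(g)
        assert f.contrast == 0.0
        assert f.energy == 1.0
        assert f.homogeneity == 1.0
        assert f.entropy == 0.0
        assert f.correlation == 0.0

    def test_perfectly_correlated_diagonal(self):
        g = GLCMatrix(
            p=np.array([[0.5, 0.0], [0.0, 0.5]]),
            levels=2, offsets=((0, 1),), symmetric=True, distance=1,
        )
        f = haralick_features(g)
        assert f.contrast == 0.0
        assert f.energy == pytest.approx(0.5)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.entropy == pytest.approx(1.0)
        assert f.correlation == pytest.approx(1.0)

    def test_checkerboard_extremes(self):
        r, c = np.mgrid[0:4, 0:4]
        board = (r + c) % 2
        g = compute_glcm(board, distance=1, angles=[0.0], symmetric=True, levels=2)
        f = haralick_features(g)
        assert f.contrast == pytest.approx(1.0)  # normalized by (L-1)^2
        assert f.correlation == pytest.approx(-1.0)

    def test_matches_loop_oracle_on_random_glcms(self, rng):
        for _ in range(50):
            L = int(rng.integers(2, 6))
            raw = rng.random((L, L)) + 1e-6
            p = raw / raw.sum()
            g = GLCMatrix(p=p, levels=L, offsets=((0, 1),), symmetric=False, distance=1)
            f = haralick_features(g)
            con, corr, ene, hom, ent = naive_features(p)
            assert f.contrast == pytest.approx(con, abs=1e-12)
            assert f.correlation == pytest.approx(corr, abs=1e-12)
            assert f.energy == pytest.approx(ene, abs=1e-12)
            assert f.homogeneity == pytest.approx(hom, abs=1e-12)
            assert f.entropy == pytest.approx(ent, abs=1e-12)

    def test_agrees_with_skimage_props(self, rng):
        """Cross-check against skimage.graycoprops conventions where they
        coincide (contrast pre-normalization, correlation, homogeneity,
        ASM)."""
        from skimage.feature import graycoprops

        qimg = rng.integers(0, 8, (32, 32))
        g = compute_glcm(qimg, distance=1, angles=[0.0], symmetric=True, levels=8)
        f = haralick_features(g)
        p4 = g.p[:, :, None, None]
        assert f.contrast * 49 == pytest.approx(graycoprops(p4, "contrast")[0, 0], rel=1e-10)
        assert f.correlation == pytest.approx(graycoprops(p4, "correlation")[0, 0], rel=1e-10)
        assert f.homogeneity == pytest.approx(graycoprops(p4, "homogeneity")[0, 0], rel=1e-10)
        assert f.energy == pytest.approx(graycoprops(p4, "ASM")[0, 0], rel=1e-10)

    def test_bound_attainment(self, rng):
        """energy <= 1 and homogeneity <= 1, with equality exactly for the
        single-cell and diagonal GLCMs."""
        for _ in range(20):
            L = int(rng.integers(2, 5))
            raw = rng.random((L, L))
            p = raw / raw.sum()
            g = GLCMatrix(p=p, levels=L, offsets=((0, 1),), symmetric=False, distance=1)
            f = haralick_features(g)
            assert f.energy <= 1.0 and f.homogeneity <= 1.0
            assert 0.0 <= f.contrast <= 1.0
            assert (f.homogeneity == 1.0) == np.allclose(p, np.diag(np.diag(p)))
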