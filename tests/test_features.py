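import numpy as np
import pytest

from leukosmear.features import (FCH_LENGTH, FCHParams, FUSED_LENGTH,
                                 GLCM_LENGTH, GLCMParams, LBP_LENGTH,
                                 LBPParams, SEGMENT_OFFSETS,
                                 cooccurrence_matrix, fch_features,
                                 fuse_features, glcm_features,
                                 haralick_statistics, lbp_histogram,
                                 ring_offsets)


def brute_lbp_histogram(arr, roi, n_bins=203, radius=2):
    """Independent double-loop evaluation of the code formula."""
    offsets = ring_offsets(radius)
    P = len(offsets)
    hist = np.zeros(n_bins)
    count = 0
    h, w = arr.shape
    for r in range(radius, h - radius):
        for c in range(radius, w - radius):
            if not roi[r, c]:
                continue
            code = 0
            for p, (dr, dc) in enumerate(offsets):
                if arr[r + dr, c + dc] - arr[r, c] >= 0:
                    code += 2**p
            hist[(code * n_bins) // 2**P] += 1
            count += 1
    return hist / count if count else hist


class TestLBP:
    def test_neighborhood_has_24_offsets(self):
        offsets = ring_offsets(2)
        assert len(offsets) == 24
        assert len(set(offsets)) == 24
        assert (0, 0) not in offsets

    def test_constant_roi_all_mass_in_last_bin(self):
        img = np.full((9, 9), 101.0)
        hist = lbp_histogram(img, np.ones((9, 9), dtype=bool))
        assert hist.shape == (LBP_LENGTH,)
        assert hist[-1] == pytest.approx(1.0)
        assert hist.sum() == pytest.approx(1.0)

    def test_invariant_to_additive_shift(self, rng):
        img = rng.uniform(0, 200, (12, 12))
        roi = rng.uniform(size=(12, 12)) < 0.7
        assert np.allclose(lbp_histogram(img, roi), lbp_histogram(img + 17.0, roi))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, (9, 9))
        roi = rng.uniform(size=(9, 9)) < 0.8
        assert np.allclose(lbp_histogram(img, roi), brute_lbp_histogram(img, roi))

    def test_seven_by_seven_toy_matrix(self):
        toy = np.array([
            [5, 9, 1, 7, 3, 8, 2],
            [6, 4, 8, 2, 9, 1, 5],
            [3, 7, 5, 6, 4, 2, 8],
            [9, 1, 2, 8, 7, 5, 3],
            [4, 6, 9, 3, 1, 8, 7],
            [2, 8, 4, 5, 6, 9, 1],
            [7, 3, 6, 1, 2, 4, 8],
        ], dtype=float)
        roi = np.ones((7, 7), dtype=bool)
        assert np.allclose(lbp_histogram(toy, roi), brute_lbp_histogram(toy, roi))

    def test_empty_roi_returns_zero_vector(self):
        hist = lbp_histogram(np.zeros((9, 9)), np.zeros((9, 9), dtype=bool))
        assert hist.shape == (LBP_LENGTH,)
        assert not hist.any()

    def test_border_pixels_excluded(self):
        # an ROI touching only the border has no full 5x5 window
        roi = np.zeros((9, 9), dtype=bool)
        roi[0, :] = True
        assert not lbp_histogram(np.zeros((9, 9)), roi).any()


def brute_haralick(P):
    """Hand-coded statistics on a tiny matrix, written independently."""
    n = P.shape[0]
    mu_x = sum(i * P[i, j] for i in range(n) for j in range(n))
    mu_y = sum(j * P[i, j] for i in range(n) for j in range(n))
    sd_x = np.sqrt(sum((i - mu_x) ** 2 * P[i, j] for i in range(n) for j in range(n)))
    sd_y = np.sqrt(sum((j - mu_y) ** 2 * P[i, j] for i in range(n) for j in range(n)))
    asm = sum(P[i, j] ** 2 for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    if sd_x > 0 and sd_y > 0:
        corr = sum((i - mu_x) * (j - mu_y) * P[i, j]
                   for i in range(n) for j in range(n)) / (sd_x * sd_y)
    else:
        corr = 0.0
    var = sum((i - mu_x) ** 2 * P[i, j] for i in range(n) for j in range(n))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]
    ent = lambda p: -sum(v * np.log(v) for v in np.ravel(p) if v > 0)
    sum_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * n - 1))
    diff_avg = sum(k * p_diff[k] for k in range(n))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(n))
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    hxy = ent(P)
    hxy1 = -sum(P[i, j] * np.log(px[i] * py[j])
                for i in range(n) for j in range(n) if P[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * np.log(px[i] * py[j])
                for i in range(n) for j in range(n) if px[i] * py[j] > 0)
    denom = max(ent(px), ent(py))
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    return np.array([asm, contrast, corr, var, idm, sum_avg, sum_var, ent(p_sum),
                     hxy, diff_var, ent(p_diff), imc1, imc2])


class TestGLCM:
    def test_constant_roi_degenerate_statistics(self):
        img = np.full((6, 6), 80.0)
        stats = glcm_features(img, np.ones((6, 6), dtype=bool))
        assert stats.shape == (GLCM_LENGTH,)
        assert stats[0] == pytest.approx(1.0)   # angular second moment
        assert stats[1] == pytest.approx(0.0)   # contrast
        assert stats[8] == pytest.approx(0.0)   # entropy

    def test_two_by_two_hand_built_matrix(self):
        img = np.array([[0.0, 0.0], [200.0, 200.0]])
        params = GLCMParams(gray_levels=2)
        P = cooccurrence_matrix(img, np.ones((2, 2), dtype=bool), (0, 1), params)
        assert np.allclose(P, [[0.5, 0.0], [0.0, 0.5]])
        stats = haralick_statistics(P)
        assert stats[0] == pytest.approx(0.5)
        assert stats[1] == pytest.approx(0.0)

    def test_matrix_symmetric_and_normalized(self, rng):
        img = rng.uniform(0, 255, (10, 10))
        roi = rng.uniform(size=(10, 10)) < 0.8
        for offset in GLCMParams().offsets:
            P = cooccurrence_matrix(img, roi, offset)
            assert P.sum() == pytest.approx(1.0)
            assert np.allclose(P, P.T)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_statistics_match_hand_coded_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, (4, 4))
        P = cooccurrence_matrix(img, np.ones((4, 4), dtype=bool), (0, 1),
                                GLCMParams(gray_levels=4))
        assert np.allclose(haralick_statistics(P), brute_haralick(P), atol=1e-9)

    def test_roi_too_sparse_returns_zero_vector(self):
        roi = np.zeros((6, 6), dtype=bool)
        roi[0, 0] = True  # no co-occurring pair at any offset
        assert not glcm_features(np.zeros((6, 6)), roi).any()

    def test_pairs_crossing_roi_boundary_excluded(self):
        img = np.zeros((2, 3))
        img[:, 2] = 255.0
        roi = np.ones((2, 3), dtype=bool)
        roi[:, 2] = False  # bright column masked out
        P = cooccurrence_matrix(img, roi, (0, 1), GLCMParams(gray_levels=2))
        assert P[0, 1] == 0.0 and P[1, 0] == 0.0


class TestFCH:
    def test_single_color_roi_single_bin(self):
        img = np.ones((5, 5, 3)) * np.array([20.0, 40.0, 60.0])
        hist = fch_features(img, np.ones((5, 5), dtype=bool))
        assert hist.shape == (FCH_LENGTH,)
        assert hist.max() == pytest.approx(1.0)
        assert (hist > 0).sum() == 1

    def test_half_and_half_split(self):
        img = np.zeros((2, 2, 3))
        img[0] = [10.0, 10.0, 10.0]     # first bin
        img[1] = [250.0, 250.0, 250.0]  # last bin
        hist = fch_features(img, np.ones((2, 2), dtype=bool))
        assert hist[0] == pytest.approx(0.5)
        assert hist[-1] == pytest.approx(0.5)

    @pytest.mark.parametrize("membership", ["crisp", "fuzzy"])
    def test_sums_to_one_and_nonnegative(self, rng, membership):
        img = rng.uniform(0, 255, (8, 8, 3))
        roi = rng.uniform(size=(8, 8)) < 0.6
        hist = fch_features(img, roi, FCHParams(membership=membership))
        assert hist.sum() == pytest.approx(1.0)
        assert np.all(hist >= 0)

    def test_invariant_to_pixel_permutation(self, rng):
        img = rng.uniform(0, 255, (6, 6, 3))
        roi = np.ones((6, 6), dtype=bool)
        base = fch_features(img, roi)
        perm = rng.permutation(36)
        shuffled = img.reshape(36, 3)[perm].reshape(6, 6, 3)
        assert np.allclose(fch_features(shuffled, roi), base)

    def test_fuzzy_mode_spreads_mass_to_neighbor_bin(self):
        # red value just below a bin boundary leaks into the adjacent red bin
        img = np.ones((3, 3, 3)) * np.array([62.0, 10.0, 10.0])  # R bin 0, near edge
        crisp = fch_features(img, np.ones((3, 3), dtype=bool))
        fuzzy = fch_features(img, np.ones((3, 3), dtype=bool),
                             FCHParams(membership="fuzzy"))
        assert (crisp > 0).sum() == 1
        assert (fuzzy > 0).sum() > 1
        assert fuzzy.sum() == pytest.approx(1.0)

    def test_empty_roi_returns_zero_vector(self):
        assert not fch_features(np.zeros((4, 4, 3)), np.zeros((4, 4), dtype=bool)).any()


class TestFusion:
    def test_lengths_and_layout(self, rng):
        lbp = rng.uniform(size=LBP_LENGTH)
        glcm = rng.uniform(size=GLCM_LENGTH)
        fch = rng.uniform(size=FCH_LENGTH)
        fused = fuse_features(lbp, glcm, fch)
        assert fused.values.shape == (FUSED_LENGTH,)
        assert SEGMENT_OFFSETS == (0, 203, 216)
        assert np.array_equal(fused.lbp, lbp)
        assert np.array_equal(fused.glcm, glcm)
        assert np.array_equal(fused.fch, fch)

    def test_all_zero_segments_fuse_to_zero_vector(self):
        fused = fuse_features(np.zeros(LBP_LENGTH), np.zeros(GLCM_LENGTH),
                              np.zeros(FCH_LENGTH))
        assert fused.values.shape == (FUSED_LENGTH,)
        assert not fused.values.any()

    def test_wrong_segment_length_names_offender(self):
        with pytest.raises(ValueError, match="glcm"):
            fuse_features(np.zeros(LBP_LENGTH), np.zeros(12), np.zeros(FCH_LENGTH))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            LBPParams(radius=2, neighbor_count=16)
        with pytest.raises(ValueError):
            GLCMParams(gray_levels=1)
        with pytest.raises(ValueError):
            FCHParams(membership="triangular")
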