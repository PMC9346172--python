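"""Histogram and texture features against brute-force tally oracles."""

from collections import deque
from itertools import product

import numpy as np
import pytest

from toporad.texture import (
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    HISTOGRAM_NAMES,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    histogram_features,
    quantize,
    texture_features,
)

# ---------------------------------------------------------------------------
# oracles


def oracle_glcm(q, roi, levels):
    """Explicit double-loop symmetric pair tally over all 2D directions."""
    P = np.zeros((levels, levels))
    H, W = q.shape
    for d in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        for i in range(H):
            for j in range(W):
                x, y = i + d[0], j + d[1]
                if 0 <= x < H and 0 <= y < W and roi[i, j] and roi[x, y]:
                    P[q[i, j] - 1, q[x, y] - 1] += 1
                    P[q[x, y] - 1, q[i, j] - 1] += 1
    return P / P.sum() if P.sum() else P


def oracle_runs(q, roi, levels, max_run):
    """Naive scan of maximal runs along each 2D direction."""
    H, W = q.shape
    R = np.zeros((levels, max_run))
    for d in [(0, 1), (1, 0), (1, 1), (1, -1)]:
        starts = []
        for i in range(H):
            for j in range(W):
                pi, pj = i - d[0], j - d[1]
                if not (0 <= pi < H and 0 <= pj < W):
                    starts.append((i, j))
        for i0, j0 in starts:
            i, j = i0, j0
            run_level, run_len = None, 0
            while 0 <= i < H and 0 <= j < W:
                lvl = q[i, j] if roi[i, j] else None
                if lvl is not None and lvl == run_level:
                    run_len += 1
                else:
                    if run_level is not None:
                        R[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lvl, (1 if lvl is not None else 0)
                i, j = i + d[0], j + d[1]
            if run_level is not None:
                R[run_level - 1, run_len - 1] += 1
    return R


def oracle_zones(q, roi, levels, max_size):
    """BFS 8-connected equal-level zones."""
    H, W = q.shape
    Z = np.zeros((levels, max_size))
    seen = np.zeros((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            if roi[i, j] and not seen[i, j]:
                lvl = q[i, j]
                size = 0
                dq = deque([(i, j)])
                seen[i, j] = True
                while dq:
                    a, b = dq.popleft()
                    size += 1
                    for di, dj in product((-1, 0, 1), repeat=2):
                        x, y = a + di, b + dj
                        if (
                            0 <= x < H and 0 <= y < W and roi[x, y]
                            and not seen[x, y] and q[x, y] == lvl
                        ):
                            seen[x, y] = True
                            dq.append((x, y))
                Z[lvl - 1, size - 1] += 1
    return Z


# ---------------------------------------------------------------------------


class TestHistogram:
    def test_energy_is_sum_of_squares(self):
        assert histogram_features([1, 2, 3])["Energy"] == 14

    def test_mean_absolute_deviation(self):
        assert histogram_features([1, 2, 3])["MeanAbsoluteDeviation"] == pytest.approx(2 / 3)

    def test_constant_vector_degenerate_conventions(self):
        f = histogram_features(np.full(10, 4.0))
        assert f["Variance"] == 0 and f["Skewness"] == 0 and f["Kurtosis"] == 0
        assert f["Entropy"] == 0

    def test_catalogue_names(self):
        f = histogram_features([1.0, 2.0, 5.0])
        assert set(f) == set(HISTOGRAM_NAMES)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            histogram_features([])


class TestQuantize:
    def test_levels_span_one_to_n(self, rng):
        img = rng.uniform(0, 100, (10, 10))
        roi = np.ones((10, 10), bool)
        q = quantize(img, roi, 8)
        assert q.min() == 1 and q.max() == 8

    def test_constant_roi_maps_to_level_one(self):
        q = quantize(np.full((5, 5), 3.0), np.ones((5, 5), bool), 32)
        assert (q == 1).all()


class TestGLCM:
    def test_checkerboard_matches_pair_counting_oracle(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        roi = np.ones((6, 6), bool)
        q = quantize(board.astype(float), roi, 2)
        P = glcm_matrix(q, roi, 2)
        P_oracle = oracle_glcm(q, roi, 2)
        assert np.allclose(P, P_oracle)
        # contrast from the oracle tally equals the feature value
        ii, jj = np.meshgrid([1, 2], [1, 2], indexing="ij")
        contrast_oracle = ((ii - jj) ** 2 * P_oracle).sum()
        feats = texture_features(board.astype(float), roi, levels=2)
        assert feats["GLCM_Contrast"] == pytest.approx(contrast_oracle)

    def test_constant_roi_single_cooccurrence_cell(self):
        feats = texture_features(np.full((6, 6), 9.0), np.ones((6, 6), bool), levels=32)
        assert feats["GLCM_JointEnergy"] == pytest.approx(1.0)
        assert feats["GLCM_Contrast"] == pytest.approx(0.0)

    def test_random_grids_match_oracle(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 50, (8, 8))
            roi = rng.uniform(size=(8, 8)) > 0.2
            roi[0, 0] = roi[5, 5] = True
            q = quantize(img, roi, 6)
            assert np.allclose(glcm_matrix(q, roi, 6), oracle_glcm(q, roi, 6))


class TestGLRLM:
    def test_single_run_rows_long_run_emphasis(self):
        """4x4 toy, each row one level: 4 horizontal runs of length 4 and
        48 single-cell runs in the other three directions, so
        LRE = (48 + 4*16)/52 and RP = 52/64."""
        img = np.repeat(np.arange(1.0, 5.0)[:, None], 4, axis=1)
        roi = np.ones((4, 4), bool)
        feats = texture_features(img, roi, levels=4)
        assert feats["GLRLM_LongRunEmphasis"] == pytest.approx(112 / 52)
        assert feats["GLRLM_RunPercentage"] == pytest.approx(52 / 64)

    def test_random_grids_match_scan_oracle(self, rng):
        for _ in range(5):
            img = rng.integers(0, 4, (7, 7)).astype(float)
            roi = rng.uniform(size=(7, 7)) > 0.2
            roi[0, 0] = roi[3, 3] = True
            q = quantize(img, roi, 4)
            R = glrlm_matrix(q, roi, 4)
            R_oracle = oracle_runs(q, roi, 4, R.shape[1])
            assert np.allclose(R, R_oracle)


class TestGLSZM:
    def test_random_grids_match_bfs_oracle(self, rng):
        for _ in range(5):
            img = rng.integers(0, 3, (8, 8)).astype(float)
            roi = rng.uniform(size=(8, 8)) > 0.15
            roi[0, 0] = roi[4, 4] = True
            q = quantize(img, roi, 3)
            Z = glszm_matrix(q, roi, 3)
            Z_oracle = oracle_zones(q, roi, 3, Z.shape[1])
            assert np.allclose(Z, Z_oracle)


class TestCatalogue:
    def test_exactly_54_features_per_image(self, rng):
        img = rng.uniform(0, 255, (12, 12))
        roi = np.ones((12, 12), bool)
        feats = texture_features(img, roi)
        assert len(feats) == 44
        assert len(histogram_features(img[roi])) == 10
        assert {n.split("_")[0] for n in feats} == {"GLCM", "GLRLM", "GLSZM"}
        assert len(GLCM_NAMES) == 22 and len(GLRLM_NAMES) == 11 and len(GLSZM_NAMES) == 11

    def test_works_in_3d(self, rng):
        img = rng.uniform(0, 255, (8, 8, 8))
        roi = np.zeros((8, 8, 8), bool)
        roi[2:6, 2:6, 2:6] = True
        feats = texture_features(img, roi, levels=8)
        assert len(feats) == 44
        assert all(np.isfinite(v) for v in feats.values())

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            texture_features(np.zeros((4, 4)), np.eye(4, dtype=bool) * 0)
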