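"""Betti-number counting and map construction against independent oracles."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.measure import euler_number

from toporad.betti import (
    BettiMapConfig,
    betti_map,
    binarize,
    build_map_stack,
    count_b0,
    count_b1,
    invert_binary,
    map_roi_from_mask,
)

# ---------------------------------------------------------------------------
# independent oracles (pure-python flood fills)


def flood_fill_components(grid: np.ndarray, value: int, diagonal: bool) -> list[set]:
    """BFS connected components of cells equal to ``value``."""
    H, W = grid.shape
    seen = np.zeros_like(grid, dtype=bool)
    if diagonal:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for i in range(H):
        for j in range(W):
            if grid[i, j] == value and not seen[i, j]:
                comp = set()
                q = deque([(i, j)])
                seen[i, j] = True
                while q:
                    a, b = q.popleft()
                    comp.add((a, b))
                    for di, dj in steps:
                        x, y = a + di, b + dj
                        if 0 <= x < H and 0 <= y < W and grid[x, y] == value and not seen[x, y]:
                            seen[x, y] = True
                            q.append((x, y))
                comps.append(comp)
    return comps


def oracle_b0(grid: np.ndarray) -> int:
    return len(flood_fill_components(grid, 1, diagonal=True))


def oracle_b1(grid: np.ndarray) -> int:
    """Zero components (4-connectivity) minus those touching the border."""
    comps = flood_fill_components(grid, 0, diagonal=False)
    H, W = grid.shape
    holes = 0
    for comp in comps:
        if not any(i in (0, H - 1) or j in (0, W - 1) for i, j in comp):
            holes += 1
    return holes


# ---------------------------------------------------------------------------


class TestBinarize:
    def test_all_bright_at_zero_threshold(self):
        assert binarize(np.full((4, 4), 255), 0).all()

    def test_zero_threshold_is_all_ones_for_any_image(self, rng):
        assert binarize(rng.integers(0, 256, (8, 8)), 0).all()

    def test_pixel_equal_to_threshold_is_foreground(self):
        assert binarize(np.array([[42]]), 42)[0, 0] == 1

    @given(st.integers(0, 255))
    @settings(max_examples=20, deadline=None)
    def test_foreground_count_nonincreasing_in_threshold(self, t):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (16, 16))
        if t < 255:
            assert binarize(img, t).sum() >= binarize(img, t + 1).sum()


class TestInvertBinary:
    def test_involution_and_conservation(self, rng):
        b = (rng.uniform(size=(12, 12)) > 0.5).astype(np.uint8)
        inv = invert_binary(b)
        assert np.array_equal(invert_binary(inv), b)
        assert b.sum() + inv.sum() == b.size

    def test_all_ones_becomes_all_zeros(self):
        assert invert_binary(np.ones((3, 3), dtype=np.uint8)).sum() == 0


class TestCounts:
    def test_diagonal_pixels_form_one_component(self):
        assert count_b0(np.array([[1, 0], [0, 1]])) == 1

    def test_empty_grid_has_no_components(self):
        assert count_b0(np.zeros((5, 5), dtype=int)) == 0

    def test_ring_has_one_hole(self):
        ring = np.ones((3, 3), dtype=int)
        ring[1, 1] = 0
        assert count_b1(ring) == 1

    def test_solid_block_has_no_holes(self):
        assert count_b1(np.ones((4, 4), dtype=int)) == 0

    def test_counts_match_flood_fill_oracles_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = (rng.uniform(size=(16, 16)) > rng.uniform(0.3, 0.7)).astype(np.uint8)
            assert count_b0(g) == oracle_b0(g)
            assert count_b1(g) == oracle_b1(g)

    def test_euler_characteristic_consistency(self):
        """B0 - B1 equals the Euler number for the 8/4-connectivity pairing,
        computed by an independent implementation."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = (rng.uniform(size=(12, 12)) > 0.5).astype(np.uint8)
            assert count_b0(g) - count_b1(g) == euler_number(g, connectivity=2)


class TestBettiMap:
    def test_map_shape_from_kernel_and_stride(self, rng):
        sl = rng.integers(0, 256, (64, 64))
        b0, b1, ratio = betti_map(sl, 128, BettiMapConfig(9, 3))
        assert b0.shape == b1.shape == ratio.shape == (19, 19)

    def test_uniform_bright_slice_gives_trivial_maps(self):
        sl = np.full((32, 32), 200)
        b0, b1, ratio = betti_map(sl, 100, BettiMapConfig(5, 3))
        assert (b0 == 1).all() and (b1 == 0).all() and (ratio == 0).all()

    def test_windows_match_bruteforce_oracle(self, rng):
        cfg = BettiMapConfig(7, 2)
        sl = rng.integers(0, 256, (32, 32))
        for t in (64, 128, 200):
            for polarity in ("original", "inverted"):
                c = BettiMapConfig(7, 2, polarity=polarity)
                b0, b1, _ = betti_map(sl, t, c)
                binar = binarize(sl, t)
                if polarity == "inverted":
                    binar = invert_binary(binar)
                for i in range(b0.shape[0]):
                    for j in range(b0.shape[1]):
                        w = binar[i * 2 : i * 2 + 7, j * 2 : j * 2 + 7]
                        assert b0[i, j] == oracle_b0(w)
                        assert b1[i, j] == oracle_b1(w)

    def test_inverted_b0_detects_enclosed_cavity(self):
        """A dark cavity below threshold makes the inverted-B0 count >= 1 in
        every window overlapping it."""
        sl = np.full((32, 32), 220)
        sl[14:18, 14:18] = 10  # enclosed cavity
        cfg = BettiMapConfig(9, 3, polarity="inverted")
        b0, _, _ = betti_map(sl, 128, cfg)
        for i in range(b0.shape[0]):
            for j in range(b0.shape[1]):
                rows = set(range(i * 3, i * 3 + 9)) & set(range(14, 18))
                cols = set(range(j * 3, j * 3 + 9)) & set(range(14, 18))
                if rows and cols:
                    assert b0[i, j] >= 1

    def test_duality_cavity_larger_than_kernel(self):
        """A cavity wider than the kernel is invisible to the original B1
        map (the hole never fits inside a window) but the inverted B0 map
        still detects it."""
        sl = np.full((48, 48), 220)
        sl[16:33, 16:33] = 10  # 17-px cavity > kernel 9
        orig = BettiMapConfig(9, 3, polarity="original")
        inv = BettiMapConfig(9, 3, polarity="inverted")
        _, b1_orig, _ = betti_map(sl, 128, orig)
        b0_inv, _, _ = betti_map(sl, 128, inv)
        assert b1_orig.sum() == 0
        assert b0_inv.max() >= 1

    def test_kernel_larger_than_slice_rejected(self):
        with pytest.raises(ValueError):
            betti_map(np.zeros((8, 8)), 0, BettiMapConfig(9, 3))


class TestMapStack:
    def test_default_config_yields_768_maps_per_polarity(self, rng):
        sl = rng.integers(0, 256, (24, 24))
        stack = build_map_stack(sl, BettiMapConfig(5, 3))
        assert stack.n_maps == 256 * 3

    def test_zero_threshold_original_b0_map_is_all_ones(self, rng):
        sl = rng.integers(0, 256, (24, 24))
        stack = build_map_stack(sl, BettiMapConfig(5, 3, thresholds=(0,)))
        assert (stack.maps[0]["B0"] == 1).all()

    def test_stack_deterministic(self, rng):
        sl = rng.integers(0, 256, (24, 24))
        cfg = BettiMapConfig(5, 3, thresholds=tuple(range(0, 256, 64)))
        s1 = build_map_stack(sl, cfg)
        s2 = build_map_stack(sl, cfg)
        for t in cfg.thresholds:
            for k in ("B0", "B1", "B1B0"):
                assert np.array_equal(s1.maps[t][k], s2.maps[t][k])

    def test_map_roi_uses_kernel_centers(self):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[10:20, 10:20] = 1
        cfg = BettiMapConfig(5, 3)
        roi = map_roi_from_mask(mask, cfg)
        for i in range(roi.shape[0]):
            for j in range(roi.shape[1]):
                assert roi[i, j] == bool(mask[i * 3 + 2, j * 3 + 2])
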