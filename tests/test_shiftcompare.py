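import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftscreen import (
    ALGORITHMS,
    block_template_search,
    brute_force_oracle,
    cyclic_overlay,
    gen_background,
    mask_monochrome,
    match_mask,
    nn_shift_counts,
    pixelwise_shift_counts,
    plant_copy,
    variance_shift_sums,
)

SCANNERS = {
    "pixelwise": pixelwise_shift_counts,
    "nearest_neighbor": nn_shift_counts,
    "variance": variance_shift_sums,
}


def reversed_grid(scores):
    """grid[(M-i) % M, (N-j) % N] for the swap-symmetry identity."""
    return np.roll(scores[::-1, ::-1], (1, 1), axis=(0, 1))


class TestCyclicOverlay:
    def test_identity_shift_pairs_each_pixel_with_itself(self):
        a = np.array([[0, 1], [2, 3]])
        aw, bw = cyclic_overlay(a, a, (0, 0))
        assert np.array_equal(aw, bw)

    def test_full_wrap_pairs_opposite_corners(self):
        a = np.array([[0, 1], [2, 3]])
        aw, bw = cyclic_overlay(a, a, (1, 1))
        assert aw.tolist() == [[0, 1], [2, 3]]
        assert bw.tolist() == [[3, 2], [1, 0]]

    def test_unequal_sizes_use_smaller_window_and_modular_indexing(self):
        a = np.arange(9).reshape(3, 3)
        b = np.arange(25).reshape(5, 5)
        aw, bw = cyclic_overlay(a, b, (4, 4))
        assert aw.shape == bw.shape == (3, 3)
        assert bw[0, 0] == b[4, 4] and bw[1, 1] == b[0, 0]

    def test_shift_outside_shift_space_rejected(self):
        a = np.zeros((2, 2), int)
        with pytest.raises(ValueError):
            cyclic_overlay(a, a, (2, 0))


class TestPixelwise:
    def test_constant_image_scores_full_window_everywhere(self):
        a = np.full((2, 2), 7)
        assert np.all(pixelwise_shift_counts(a, a).scores == 4)

    def test_distinct_values_match_only_at_identity(self):
        a = np.array([[0, 1], [2, 3]])
        assert pixelwise_shift_counts(a, a).scores.tolist() == [[4, 0], [0, 0]]

    def test_two_level_histogram_sum(self):
        # 4x4 images holding eight 5s and eight 9s each: summed over all
        # 16 shifts the matches must be 8*8 + 8*8 = 128.
        a = np.array([[5] * 4, [9] * 4, [5] * 4, [9] * 4])
        b = np.array([[5, 9] * 2] * 4)
        assert pixelwise_shift_counts(a, b).scores.sum() == 128

    @given(seed=st.integers(0, 200))
    @settings(max_examples=25)
    def test_histogram_conservation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 16, size=(8, 8))
        b = rng.integers(0, 16, size=(8, 8))
        total = pixelwise_shift_counts(a, b).scores.sum()
        ha = np.bincount(a.ravel(), minlength=16)
        hb = np.bincount(b.ravel(), minlength=16)
        assert total == int((ha * hb).sum())


class TestNearestNeighbor:
    def test_constant_image_scores_interior_anchor_count(self):
        a = np.full((4, 4), 3)
        assert np.all(nn_shift_counts(a, a).scores == 4)  # (4-2)*(4-2)

    def test_all_distinct_levels_match_only_at_zero_shift(self):
        a = np.arange(16).reshape(4, 4)
        g = nn_shift_counts(a, a).scores
        assert g[0, 0] == 4
        assert g.sum() == 4

    def test_planted_copy_scores_at_least_interior_anchors(self):
        bg = gen_background(50, 50, 0, 255, 11)
        img, shift = plant_copy(bg, (5, 5, 10, 10), (25, 10))
        assert shift == (20, 5)
        assert nn_shift_counts(img, img).scores[shift] >= 64  # (10-2)^2

    def test_window_below_3x3_rejected(self):
        with pytest.raises(ValueError):
            nn_shift_counts(np.zeros((2, 5), int), np.zeros((2, 5), int))


class TestVariance:
    def test_self_comparison_is_zero_at_zero_shift(self):
        a = gen_background(8, 8, 0, 255, 5)
        assert variance_shift_sums(a, a).scores[0, 0] == 0.0

    def test_constant_brightness_offset_scores_zero(self):
        a = gen_background(8, 8, 50, 150, 6)
        assert variance_shift_sums(a, a + 10).scores[0, 0] == 0.0

    def test_single_outlier_block_hand_computed(self):
        # 3x3 all-zero vs all-zero with center 9.  Every toroidal 3x3
        # block of the difference image is a permutation of the nine
        # values {eight 0s, one -9}: mean -1, population variance
        # (8*1 + 64)/9 = 8.  Nine blocks -> score 72.
        a = np.zeros((3, 3), int)
        b = a.copy()
        b[1, 1] = 9
        assert variance_shift_sums(a, b).scores[0, 0] == pytest.approx(72.0)

    def test_brightness_invariance_at_every_shift(self):
        a = gen_background(10, 10, 20, 180, 7)
        base = variance_shift_sums(a, a).scores
        for c in (1, 10, 50):
            offset = variance_shift_sums(a, a + c).scores
            assert np.allclose(offset, base, rtol=0, atol=1e-9)

    def test_masked_input_rejected_with_guidance(self):
        masked = mask_monochrome(np.full((4, 4), 255))
        with pytest.raises(ValueError, match="pixelwise or nearest-neighbor"):
            variance_shift_sums(masked, masked)


class TestMatchMask:
    def test_self_identity_shift_is_all_true(self):
        a = gen_background(5, 5, 0, 255, 8)
        mm = match_mask(a, a, (0, 0), "pixelwise")
        assert mm.mask.all() and mm.count == 25

    def test_distinct_values_off_shift_all_false(self):
        a = np.array([[0, 1], [2, 3]])
        assert match_mask(a, a, (0, 1), "pixelwise").count == 0

    def test_counts_equal_grid_entries(self):
        a = gen_background(12, 12, 0, 7, 9)
        b = gen_background(12, 12, 0, 7, 10)
        gp = pixelwise_shift_counts(a, b).scores
        gn = nn_shift_counts(a, b).scores
        for shift in [(0, 0), (3, 7), (11, 1)]:
            assert match_mask(a, b, shift, "pixelwise").count == gp[shift]
            assert match_mask(a, b, shift, "nearest_neighbor").count == gn[shift]

    def test_planted_copy_mask_covers_the_rectangle(self):
        bg = gen_background(60, 60, 64, 127, 12)
        img, shift = plant_copy(bg, (4, 6, 12, 9), (30, 40))
        mm = match_mask(img, img, shift, "pixelwise")
        assert mm.mask[4:16, 6:15].all()
        assert mm.count >= 12 * 9

    def test_variance_is_unsupported(self):
        a = np.zeros((4, 4), int)
        with pytest.raises(ValueError):
            match_mask(a, a, (0, 0), "variance")


class TestBlockTemplateSearch:
    def test_whole_image_block_matches_only_itself(self):
        a = gen_background(6, 7, 0, 255, 13)
        assert block_template_search(a, (0, 0), 6, 7) == [(0, 0)]

    def test_planted_block_found_at_both_positions(self):
        bg = gen_background(20, 20, 0, 255, 14)
        img, _ = plant_copy(bg, (2, 2, 5, 4), (10, 7))
        assert block_template_search(img, (2, 2), 5, 4) == [(2, 2), (10, 7)]

    def test_unique_block_returns_anchor_only(self):
        a = np.arange(64).reshape(8, 8) % 251
        assert block_template_search(a, (3, 3), 3, 3) == [(3, 3)]

    def test_out_of_bounds_block_rejected(self):
        with pytest.raises(ValueError):
            block_template_search(np.zeros((5, 5), int), (3, 3), 3, 3)


class TestOracleEquivalence:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_optimized_equals_brute_force(self, algorithm):
        rng = np.random.default_rng(99)
        for _ in range(10):
            ra, ca = rng.integers(4, 13, size=2)
            rb, cb = (ra, ca) if rng.random() < 0.5 else rng.integers(4, 13, size=2)
            a = rng.integers(0, 256, size=(ra, ca))
            b = rng.integers(0, 256, size=(rb, cb))
            got = SCANNERS[algorithm](a, b).scores
            want = brute_force_oracle(a, b, algorithm).scores
            if algorithm == "variance":
                assert np.allclose(got, want, rtol=1e-9, atol=1e-9)
            else:
                assert np.array_equal(got, want)

    def test_oracle_agrees_on_masked_inputs(self):
        rng = np.random.default_rng(123)
        a = mask_monochrome(rng.integers(0, 4, size=(6, 6)) * 85, {0, 255})
        assert a.sentinel_count > 0
        for algorithm in ("pixelwise", "nearest_neighbor"):
            got = SCANNERS[algorithm](a, a).scores
            want = brute_force_oracle(a, a, algorithm).scores
            assert np.array_equal(got, want)


class TestGridInvariants:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_swap_symmetry(self, algorithm):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 64, size=(11, 9))
        b = rng.integers(0, 64, size=(11, 9))
        g_ab = SCANNERS[algorithm](a, b).scores
        g_ba = SCANNERS[algorithm](b, a).scores
        assert np.allclose(g_ab, reversed_grid(g_ba), rtol=0, atol=1e-9)

    def test_self_comparison_identities(self, rng):
        for _ in range(5):
            a = rng.integers(0, 256, size=(7, 8))
            assert pixelwise_shift_counts(a, a).scores[0, 0] == 56
            assert nn_shift_counts(a, a).scores[0, 0] == 30  # (7-2)*(8-2)
            assert variance_shift_sums(a, a).scores[0, 0] == 0.0

    def test_nn_hit_implies_at_least_nine_pixel_matches(self, rng):
        a = rng.integers(0, 4, size=(10, 10))
        b = rng.integers(0, 4, size=(10, 10))
        gp = pixelwise_shift_counts(a, b).scores
        gn = nn_shift_counts(a, b).scores
        assert np.all(gp[gn > 0] >= 9)

    def test_score_ranges(self, rng):
        a = rng.integers(0, 8, size=(9, 9))
        b = rng.integers(0, 8, size=(9, 9))
        gp = pixelwise_shift_counts(a, b).scores
        gn = nn_shift_counts(a, b).scores
        gv = variance_shift_sums(a, b).scores
        assert gp.min() >= 0 and gp.max() <= 81
        assert gn.min() >= 0 and gn.max() <= 49
        assert gv.min() >= 0
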