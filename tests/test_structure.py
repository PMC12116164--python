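"""Tiling, background filtering, pixel counts and structural ratios."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orchardfusion.structure import (ClassPixelCounts, count_class_pixels,
                                     filter_background_tiles, mean_ratios,
                                     structural_ratios, tile_image)
from orchardfusion.synthetic import LABELS, SceneSpec, generate_scene


class TestTiling:
    def test_exact_division_tile_count(self):
        image = np.zeros((1024, 1536, 3), dtype=np.uint8)
        for policy in ("pad_white", "pad_reflect", "drop_partial"):
            grid = tile_image(image, tile_size=512, pad_policy=policy)
            assert len(grid) == 6

    def test_partial_tiles_padded_white(self):
        image = np.zeros((1000, 1300, 3), dtype=np.uint8)
        mask = np.ones((1000, 1300), dtype=np.uint8)
        grid = tile_image(image, mask, tile_size=512, pad_policy="pad_white")
        assert len(grid) == 6
        corner = [t for t in grid.tiles if (t.row, t.col) == (1, 2)][0]
        assert corner.valid_h == 1000 - 512 and corner.valid_w == 1300 - 1024
        # padded image pixels are white backdrop, padded mask pixels background
        assert (corner.image[corner.valid_h:, :] == 255).all()
        assert (corner.mask[corner.valid_h:, :] == LABELS["background"]).all()

    def test_drop_partial_on_small_image_warns_and_yields_no_tiles(self):
        image = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.warns(UserWarning):
            grid = tile_image(image, tile_size=512, pad_policy="drop_partial")
        assert len(grid) == 0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((4, 4, 3)), tile_size=0)
        with pytest.raises(ValueError):
            tile_image(np.zeros((4, 4, 3)), np.zeros((5, 5)), tile_size=2)
        with pytest.raises(ValueError):
            tile_image(np.zeros((4, 4, 3)), tile_size=2, pad_policy="wrap")


class TestBackgroundFilter:
    def test_pure_white_tile_dropped_and_leafy_tile_kept(self):
        white = np.full((8, 8, 3), 255, dtype=np.uint8)
        leafy = white.copy()
        leafy[:4, :, :] = (60, 140, 60)      # half leaf pixels
        grid = tile_image(np.vstack([white, leafy]), tile_size=8)
        kept = filter_background_tiles(grid)
        assert len(grid) == 2 and len(kept) == 1
        assert kept.tiles[0].row == 1

    def test_organs_confined_to_centre_tile(self):
        """3x3 tiling with content only in the centre: exactly 1 tile kept."""
        size = 96
        image = np.full((size, size, 3), 250, dtype=np.uint8)
        image[40:56, 40:56] = (60, 140, 60)
        grid = tile_image(image, tile_size=32)
        kept = filter_background_tiles(grid, whiteness_threshold=240,
                                       min_foreground_fraction=0.01)
        # oracle: count non-white pixels tile by tile
        expected = [(r, c) for r in range(3) for c in range(3)
                    if (image[32 * r:32 * r + 32, 32 * c:32 * c + 32] < 240)
                    .all(axis=-1).mean() >= 0.01]
        assert [(t.row, t.col) for t in kept.tiles] == expected == [(1, 1)]

    def test_threshold_validation(self):
        grid = tile_image(np.zeros((8, 8, 3), dtype=np.uint8), tile_size=8)
        with pytest.raises(ValueError):
            filter_background_tiles(grid, whiteness_threshold=300)
        with pytest.raises(ValueError):
            filter_background_tiles(grid, min_foreground_fraction=2.0)


class TestCounts:
    def test_direct_tally(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[:5, :20] = LABELS["flower"]     # 100 px
        mask[10:25, :20] = LABELS["leaf"]    # 300 px
        mask[30:35, :20] = LABELS["branch"]  # 100 px
        counts = count_class_pixels([mask], "flowering")
        assert (counts.flower_or_fruit, counts.leaf, counts.trunk) == (100, 300, 100)
        assert counts.canopy_total == 500

    def test_all_background_masks_count_zero(self):
        counts = count_class_pixels([np.zeros((8, 8), dtype=np.uint8)], "young_fruit")
        assert counts.canopy_total == 0 and counts.background == 64

    def test_off_stage_labels_warn_and_count_zero(self):
        mask = np.full((4, 4), LABELS["fruit"], dtype=np.uint8)
        with pytest.warns(UserWarning):
            counts = count_class_pixels([mask], "flowering")
        assert counts.flower_or_fruit == 0

    def test_tiled_counts_match_generator_ledger(self):
        scene = generate_scene(SceneSpec(width=150, height=90, seed=11))
        grid = tile_image(scene.image, scene.mask, tile_size=64)  # padded tiles
        counts = count_class_pixels(grid, "flowering")
        assert counts.flower_or_fruit == scene.true_counts[LABELS["flower"]]
        assert counts.leaf == scene.true_counts[LABELS["leaf"]]
        assert counts.trunk == scene.true_counts[LABELS["branch"]]
        assert counts.background == scene.true_counts[0]


class TestRatios:
    def test_flowering_hand_case(self):
        counts = ClassPixelCounts(stage="flowering", flower_or_fruit=100,
                                  leaf=300, trunk=100)
        r = structural_ratios(counts)
        assert r.f1 == pytest.approx(0.2)
        assert r.f2 == pytest.approx(1 / 3)
        assert r.f3 is None and r.f4 is None

    def test_zero_numerator_convention(self):
        counts = ClassPixelCounts(stage="young_fruit", flower_or_fruit=0,
                                  leaf=500, trunk=100)
        r = structural_ratios(counts)
        assert r.f3 == 0.0 and r.f4 == 0.0

    def test_degenerate_denominators_raise(self):
        with pytest.raises(ZeroDivisionError):
            structural_ratios(ClassPixelCounts(stage="flowering"))
        with pytest.raises(ZeroDivisionError):
            structural_ratios(ClassPixelCounts(stage="flowering",
                                               flower_or_fruit=10, leaf=0, trunk=5))

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 10 ** 6), st.integers(1, 10 ** 6), st.integers(0, 10 ** 6))
    def test_matches_exact_fraction_arithmetic(self, F, I, G):
        counts = ClassPixelCounts(stage="flowering", flower_or_fruit=F,
                                  leaf=I, trunk=G)
        r = structural_ratios(counts)
        assert abs(r.f1 - Fraction(F, F + I + G)) < 1e-15
        assert abs(r.f2 - (Fraction(F, I) if F else 0)) < 1e-15
        # class shares partition the canopy exactly
        assert r.f1 + I / (F + I + G) + G / (F + I + G) == pytest.approx(1.0, abs=1e-12)

    def test_adding_flower_pixels_increases_both_ratios(self):
        lo = structural_ratios(ClassPixelCounts("flowering", 50, 300, 100))
        hi = structural_ratios(ClassPixelCounts("flowering", 80, 300, 100))
        assert hi.f1 > lo.f1 and hi.f2 > lo.f2

    def test_ratios_invariant_to_tiling(self):
        scene = generate_scene(SceneSpec(width=130, height=70, seed=2))
        whole = structural_ratios(count_class_pixels([scene.mask], "flowering"))
        for t in (32, 50, 64):
            grid = tile_image(scene.image, scene.mask, tile_size=t)
            tiled = structural_ratios(count_class_pixels(grid, "flowering"))
            assert tiled.f1 == whole.f1 and tiled.f2 == whole.f2

    def test_plot_mean_aggregation(self):
        a = structural_ratios(ClassPixelCounts("flowering", 100, 300, 100))
        b = structural_ratios(ClassPixelCounts("flowering", 200, 200, 100))
        agg = mean_ratios([a, b])
        assert agg.f1 == pytest.approx((a.f1 + b.f1) / 2)
        assert agg.f3 is None
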