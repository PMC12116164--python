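"""Canopy structural features from segmentation masks.

Whole-tree photos are tiled into fixed-size patches (512 px in the field
protocol; configurable), background-only tiles are dropped, per-class pixel
counts are pooled over the kept tiles, and four structural ratios follow:

    SA = FA + IA + GA          (flowering canopy:  flower + leaf + trunk)
    SB = FB + IB + GB          (young-fruit canopy: fruit + leaf + trunk)
    f1 = FA / SA               flower area ratio
    f2 = FA / IA               flower-to-leaf ratio
    f3 = FB / SB               fruit area ratio
    f4 = FB / IB               fruit-to-leaf ratio

Zero-numerator ratios are reported as 0; zero denominators raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import LABELS

__all__ = ["Tile", "TileGrid", "ClassPixelCounts", "StructuralRatios",
           "tile_image", "filter_background_tiles", "count_class_pixels",
           "structural_ratios", "mean_ratios"]

PAD_POLICIES = ("pad_reflect", "pad_white", "drop_partial")


@dataclass
class Tile:
    row: int
    col: int
    image: np.ndarray
    mask: np.ndarray | None = None
    valid_h: int = 0      # rows of original (un-padded) content
    valid_w: int = 0


@dataclass
class TileGrid:
    tile_size: int
    pad_policy: str
    tiles: list = field(default_factory=list)

    def __len__(self):
        return len(self.tiles)


@dataclass
class ClassPixelCounts:
    stage: str
    flower_or_fruit: int = 0     # FA (flowering) or FB (young fruit)
    leaf: int = 0                # IA or IB
    trunk: int = 0               # GA or GB
    background: int = 0

    @property
    def canopy_total(self) -> int:
        """SA or SB: organ pixels summed."""
        return self.flower_or_fruit + self.leaf + self.trunk


@dataclass
class StructuralRatios:
    f1: float | None = None
    f2: float | None = None
    f3: float | None = None
    f4: float | None = None


def tile_image(image, mask=None, tile_size: int = 512,
               pad_policy: str = "pad_white",
               background_value: int = 255) -> TileGrid:
    """Split an H x W (x3) image (and aligned mask) into tile_size squares.

    Partial edge tiles are padded (reflect or white backdrop) or dropped;
    padded mask pixels are labelled background and excluded from counts via
    each tile's (valid_h, valid_w).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if pad_policy not in PAD_POLICIES:
        raise ValueError(f"pad_policy must be one of {PAD_POLICIES}")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape[:2] != image.shape[:2]:
            raise ValueError("image/mask dimensions differ")

    h, w = image.shape[:2]
    t = tile_size
    if pad_policy == "drop_partial":
        n_rows, n_cols = h // t, w // t
        if n_rows == 0 or n_cols == 0:
            warnings.warn(f"image {h}x{w} smaller than tile size {t}; no tiles kept")
    else:
        n_rows, n_cols = -(-h // t), -(-w // t)

    grid = TileGrid(tile_size=t, pad_policy=pad_policy)
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * t, c * t
            img_patch = image[y0:y0 + t, x0:x0 + t]
            vh, vw = img_patch.shape[:2]
            if (vh, vw) != (t, t):
                pad_spec = [(0, t - vh), (0, t - vw)] + [(0, 0)] * (image.ndim - 2)
                if pad_policy == "pad_reflect":
                    img_patch = np.pad(img_patch, pad_spec, mode="reflect")
                else:
                    img_patch = np.pad(img_patch, pad_spec, mode="constant",
                                       constant_values=background_value)
            mask_patch = None
            if mask is not None:
                mask_patch = mask[y0:y0 + t, x0:x0 + t]
                if mask_patch.shape != (t, t):
                    mask_patch = np.pad(
                        mask_patch, [(0, t - mask_patch.shape[0]), (0, t - mask_patch.shape[1])],
                        mode="constant", constant_values=LABELS["background"])
            grid.tiles.append(Tile(row=r, col=c, image=img_patch, mask=mask_patch,
                                   valid_h=vh, valid_w=vw))
    return grid


def filter_background_tiles(grid: TileGrid, whiteness_threshold: int = 240,
                            min_foreground_fraction: float = 0.01) -> TileGrid:
    """Drop tiles that are (almost) pure white backdrop.

    A pixel is "white" when every channel is >= whiteness_threshold; a tile
    is kept when its white fraction over the un-padded region is strictly
    below 1 - min_foreground_fraction.
    """
    if len(grid) == 0:
        raise ValueError("empty tile grid")
    if not (0 <= whiteness_threshold <= 255):
        raise ValueError("whiteness_threshold must lie in [0, 255]")
    if not (0.0 <= min_foreground_fraction <= 1.0):
        raise ValueError("min_foreground_fraction must lie in [0, 1]")
    kept = TileGrid(tile_size=grid.tile_size, pad_policy=grid.pad_policy)
    for tile in grid.tiles:
        patch = np.asarray(tile.image)[:tile.valid_h, :tile.valid_w]
        if patch.ndim == 2:
            white = patch >= whiteness_threshold
        else:
            white = (patch >= whiteness_threshold).all(axis=-1)
        if white.mean() < 1.0 - min_foreground_fraction:
            kept.tiles.append(tile)
    return kept


def count_class_pixels(mask_tiles, stage: str) -> ClassPixelCounts:
    """Pool per-label pixel counts over tiles (padded pixels excluded).

    `mask_tiles` may be a TileGrid (with masks), a list of Tile, or a list
    of bare 2-D label arrays in the unified 5-label space.
    """
    if stage not in ("flowering", "young_fruit"):
        raise ValueError(f"unknown stage {stage!r}")
    if isinstance(mask_tiles, TileGrid):
        mask_tiles = mask_tiles.tiles
    mask_tiles = list(mask_tiles)
    if not mask_tiles:
        raise ValueError("no mask tiles")
    counts = np.zeros(5, dtype=np.int64)
    for item in mask_tiles:
        if isinstance(item, Tile):
            if item.mask is None:
                raise ValueError("tile carries no mask")
            m = np.asarray(item.mask)[:item.valid_h, :item.valid_w]
        else:
            m = np.asarray(item)
        if m.min() < 0 or m.max() > 4:
            raise ValueError("mask labels outside the unified 5-label space")
        counts += np.bincount(m.ravel(), minlength=5)

    organ = LABELS["flower"] if stage == "flowering" else LABELS["fruit"]
    off_stage = LABELS["fruit"] if stage == "flowering" else LABELS["flower"]
    if counts[off_stage] > 0:
        warnings.warn(
            f"stage {stage!r} masks contain {int(counts[off_stage])} pixels of the "
            "other stage's organ label; counted as 0 for this stage")
    return ClassPixelCounts(
        stage=stage,
        flower_or_fruit=int(counts[organ]),
        leaf=int(counts[LABELS["leaf"]]),
        trunk=int(counts[LABELS["branch"]]),
        background=int(counts[LABELS["background"]]),
    )


def structural_ratios(counts: ClassPixelCounts) -> StructuralRatios:
    """Compute f1/f2 (flowering) or f3/f4 (young fruit) from pooled counts."""
    total = counts.canopy_total
    if total == 0:
        raise ZeroDivisionError(
            f"undefined ratios: no canopy pixels at stage {counts.stage!r}")
    F, I = counts.flower_or_fruit, counts.leaf
    area_ratio = F / total
    if F == 0:
        leaf_ratio = 0.0       # zero-numerator convention
    elif I == 0:
        raise ZeroDivisionError(
            f"undefined flower/fruit-to-leaf ratio: no leaf pixels but {F} organ pixels")
    else:
        leaf_ratio = F / I
    if counts.stage == "flowering":
        return StructuralRatios(f1=area_ratio, f2=leaf_ratio)
    return StructuralRatios(f3=area_ratio, f4=leaf_ratio)


def mean_ratios(ratios_list) -> StructuralRatios:
    """Plot-level aggregation: mean of per-tree ratios, fieldwise."""
    ratios_list = list(ratios_list)
    if not ratios_list:
        raise ValueError("no ratios to aggregate")
    out = StructuralRatios()
    for name in ("f1", "f2", "f3", "f4"):
        vals = [getattr(r, name) for r in ratios_list if getattr(r, name) is not None]
        if vals:
            setattr(out, name, float(np.mean(vals)))
    return out
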