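"""Vegetation indices from visible and multispectral rasters.

Visible-light indices operate on per-pixel chromatic coordinates

    r = rt / (rt + gt + bt),  g, b analogous,

computed from the raw visible digital numbers first, which makes them
invariant to any positive scaling of the raw bands.  The six visible and
six multispectral indices:

    VARI  = (g - r) / (g + r - b)        DVI   = NIR - R
    ExR   = 1.4 r - g                    GDVI  = NIR - G
    ExG   = 2 g - r - b                  EVI   = 2.5 (NIR - R) / (NIR + 6 R - 7.5 B + 1)
    GLI   = (2 g - b - r) / (2 g + b + r)  GEVI = 2.5 (NIR - G) / (NIR + 6 G - 7.5 B + 1)
    NDI   = (g - r) / (g + r)            NDVI  = (NIR - R) / (NIR + R)
    MGRVI = (g^2 - r^2) / (g^2 + r^2)    GNDVI = (NIR - B) / (NIR + B)

GNDVI is implemented with the blue band as the source protocol prints it;
the more common green-band variant is available behind ``green_gndvi``.
Pixels with an undefined denominator become nodata (NaN) for that index
only.  Zonal aggregation is the mean of valid pixels whose centres fall
inside the plot polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["BandStack", "NormalizedRGB", "VISIBLE_INDEX_NAMES",
           "MULTISPECTRAL_INDEX_NAMES", "INDEX_ALIASES",
           "normalize_rgb", "visible_indices", "multispectral_indices",
           "zonal_index", "load_band_stack", "write_index_table"]

VISIBLE_INDEX_NAMES = ("VARI", "ExR", "ExG", "GLI", "NDI", "MGRVI")
MULTISPECTRAL_INDEX_NAMES = ("DVI", "GDVI", "EVI", "GEVI", "NDVI", "GNDVI")
EXTENDED_VISIBLE = ("ExGR", "RGBVI")
EXTENDED_MULTISPECTRAL = ("GRVI", "RVI")

# model-input aliases for the screened indices
INDEX_ALIASES = {"DVI": "d1", "GDVI": "d2", "GEVI": "d3", "VARI": "k1"}


@dataclass
class BandStack:
    """Named 2-D bands; `transform` maps pixel (col,row) centres to (x,y).

    transform = (x_origin, pixel_width, y_origin, pixel_height); the centre
    of pixel (row, col) sits at (x_origin + (col + 0.5) * pixel_width,
    y_origin + (row + 0.5) * pixel_height).
    """
    bands: dict
    transform: tuple = (0.0, 1.0, 0.0, 1.0)
    nodata: float | None = None

    def __post_init__(self):
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError(f"bands have mismatched shapes: {shapes}")

    @property
    def shape(self):
        return next(iter(self.bands.values())).shape

    def band(self, name):
        arr = np.asarray(self.bands[name], dtype=np.float64)
        if self.nodata is not None:
            arr = np.where(arr == self.nodata, np.nan, arr)
        return arr


@dataclass
class NormalizedRGB:
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray


def _safe_divide(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den == 0, np.nan, out)


def normalize_rgb(stack: BandStack) -> NormalizedRGB:
    """Per-pixel chromatic coordinates; all-zero pixels become nodata."""
    for name in ("R", "G", "B"):
        if name not in stack.bands:
            raise ValueError(f"band {name!r} missing from stack")
    rt, gt, bt = stack.band("R"), stack.band("G"), stack.band("B")
    total = rt + gt + bt
    return NormalizedRGB(r=_safe_divide(rt, total),
                         g=_safe_divide(gt, total),
                         b=_safe_divide(bt, total))


def visible_indices(norm: NormalizedRGB, extended: bool = False) -> dict:
    r, g, b = norm.r, norm.g, norm.b
    out = {
        "VARI": _safe_divide(g - r, g + r - b),
        "ExR": 1.4 * r - g,
        "ExG": 2.0 * g - r - b,
        "GLI": _safe_divide(2.0 * g - b - r, 2.0 * g + b + r),
        "NDI": _safe_divide(g - r, g + r),
        "MGRVI": _safe_divide(g ** 2 - r ** 2, g ** 2 + r ** 2),
    }
    if extended:
        out["ExGR"] = out["ExG"] - out["ExR"]
        out["RGBVI"] = _safe_divide(g ** 2 - b * r, g ** 2 + b * r)
    return out


def multispectral_indices(stack: BandStack, extended: bool = False,
                          green_gndvi: bool = False) -> dict:
    if "NIR" not in stack.bands:
        raise ValueError("band 'NIR' missing from stack")
    nir = stack.band("NIR")
    r = stack.band("R")
    g = stack.band("G")
    b = stack.band("B")
    gndvi_other = g if green_gndvi else b
    out = {
        "DVI": nir - r,
        "GDVI": nir - g,
        "EVI": _safe_divide(2.5 * (nir - r), nir + 6.0 * r - 7.5 * b + 1.0),
        "GEVI": _safe_divide(2.5 * (nir - g), nir + 6.0 * g - 7.5 * b + 1.0),
        "NDVI": _safe_divide(nir - r, nir + r),
        "GNDVI": _safe_divide(nir - gndvi_other, nir + gndvi_other),
    }
    if extended:
        out["GRVI"] = _safe_divide(nir - g, nir + g)
        out["RVI"] = _safe_divide(nir, r)
    return out


def zonal_index(index_map: np.ndarray, polygon,
                transform: tuple = (0.0, 1.0, 0.0, 1.0)) -> tuple:
    """Mean of valid pixels whose centres fall in `polygon`; returns (mean, n).

    `polygon` is a shapely geometry or a GeoJSON-like mapping.
    """
    import shapely
    from shapely.geometry import shape as geo_shape
    from shapely.geometry.base import BaseGeometry

    if not isinstance(polygon, BaseGeometry):
        polygon = geo_shape(polygon)
    index_map = np.asarray(index_map, dtype=np.float64)
    h, w = index_map.shape
    x0, px, y0, py = transform
    xs = x0 + (np.arange(w) + 0.5) * px
    ys = y0 + (np.arange(h) + 0.5) * py
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(polygon, xx.ravel(), yy.ravel()).reshape(h, w)
    vals = index_map[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("polygon covers no valid index pixels")
    return float(vals.mean()), int(vals.size)


def load_band_stack(path, band_order=("B", "G", "R", "NIR"),
                    transform=(0.0, 1.0, 0.0, 1.0)) -> BandStack:
    """Read a multiband TIFF written band-first into a BandStack."""
    import tifffile
    arr = np.asarray(tifffile.imread(Path(path)), dtype=np.float64)
    if arr.ndim != 3 or arr.shape[0] != len(band_order):
        raise ValueError(f"expected a {len(band_order)}-band raster, got shape {arr.shape}")
    return BandStack(bands={name: arr[i] for i, name in enumerate(band_order)},
                     transform=transform)


def write_index_table(rows, path):
    """Per-plot index table CSV: plot_id followed by the twelve indices."""
    import pandas as pd
    cols = ["plot_id", *VISIBLE_INDEX_NAMES, *MULTISPECTRAL_INDEX_NAMES]
    df = pd.DataFrame(rows)
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(Path(path), index=False)
    return df
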