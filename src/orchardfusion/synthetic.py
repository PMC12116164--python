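"""Synthetic orchard data with known ground truth.

Three generators stand in for field data that was never deposited:

* ``generate_scene`` draws a procedural fruit-tree photo against a white
  backdrop — recursive branch segments, elliptical leaf blobs and disc
  flowers/fruits — compositing shapes in a fixed z-order (branch < leaf <
  flower/fruit) so the label mask and per-class pixel counts are exact by
  construction.
* ``generate_reflectance`` produces a 4-band (B, G, R, NIR) reflectance
  raster whose band means are affine functions of a latent plot vigor, plus
  optional spatially correlated noise.
* ``generate_plot_dataset`` samples per-plot records where yield is a known
  linear function (plus Gaussian noise) of SPAD, structural ratios and
  vegetation indices, enabling parameter-recovery tests.

Every generator is bit-reproducible for a given spec + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LABELS", "LABEL_NAMES", "FEATURE_ORDER", "DEFAULT_BETA", "DEFAULT_INTERCEPT",
    "SceneSpec", "SegScene", "PlotTruth",
    "generate_scene", "generate_reflectance", "generate_plot_dataset",
    "band_means", "plot_indices_from_vigor",
    "save_scene", "load_scene", "save_raster", "load_raster",
    "plots_to_frame", "save_plot_table",
]

LABELS = {"background": 0, "flower": 1, "fruit": 2, "leaf": 3, "branch": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

# Indexed-PNG palette: white backdrop, pink flower, pale bagged fruit,
# green leaf, brown branch.
PALETTE = {
    0: (250, 250, 250),
    1: (232, 96, 136),
    2: (214, 192, 140),
    3: (62, 138, 62),
    4: (104, 72, 42),
}

FEATURE_ORDER = ["s1", "s2", "f1", "f2", "f3", "f4", "d1", "d2", "d3", "k1"]

# Generative yield model: yield_kg = intercept + beta . features + N(0, sd).
# Coefficients chosen once to give plot yields in the ~100-400 kg range the
# study system reports, with all three feature groups contributing.
DEFAULT_INTERCEPT = -120.0
DEFAULT_BETA = np.array([
    3.0,    # s1 (kg per SPAD unit)
    2.0,    # s2
    110.0,  # f1
    55.0,   # f2
    90.0,   # f3
    140.0,  # f4
    80.0,   # d1 = DVI
    60.0,   # d2 = GDVI
    45.0,   # d3 = GEVI
    40.0,   # k1 = VARI
])
DEFAULT_NOISE_SD = 5.0   # kg


@dataclass(frozen=True)
class SceneSpec:
    width: int = 128
    height: int = 128
    stage: str = "flowering"           # or "young_fruit"
    n_flowers_or_fruits: int = 12
    leaf_coverage: float = 0.30
    branch_thickness: float = 5.0
    background_value: int = 250
    seed: int = 0
    organ_radius: float = 9.0          # mean disc radius of flowers/fruits

    def validate(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if not (0.0 <= self.leaf_coverage <= 1.0):
            raise ValueError("leaf_coverage must lie in [0, 1]")
        if self.stage not in ("flowering", "young_fruit"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.n_flowers_or_fruits < 0 or self.branch_thickness < 0:
            raise ValueError("counts and thickness must be non-negative")
        return self


@dataclass
class SegScene:
    image: np.ndarray        # H x W x 3 uint8
    mask: np.ndarray         # H x W uint8 labels
    true_counts: np.ndarray  # length-5 pixel counts per label
    spec: SceneSpec | None = None


@dataclass
class PlotTruth:
    plot_id: str
    latent_vigor: float
    s1: float
    s2: float
    f1: float
    f2: float
    f3: float
    f4: float
    d1: float
    d2: float
    d3: float
    k1: float
    yield_kg: float
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = DEFAULT_NOISE_SD

    def features(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_ORDER])


# ---------------------------------------------------------------------------
# scene drawing primitives (exact vectorised rasterisation)
# ---------------------------------------------------------------------------

def _grid(h, w):
    yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    return yy, xx


def _disc_mask(h, w, cy, cx, radius):
    yy, xx = _grid(h, w)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _ellipse_mask(h, w, cy, cx, a, b, theta):
    yy, xx = _grid(h, w)
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _capsule_mask(h, w, p0, p1, thickness):
    """Pixels within thickness/2 of segment p0-p1 (p = (y, x))."""
    yy, xx = _grid(h, w)
    y0, x0 = p0
    y1, x1 = p1
    dy, dx = y1 - y0, x1 - x0
    L2 = dy * dy + dx * dx
    if L2 == 0:
        return _disc_mask(h, w, y0, x0, thickness / 2.0)
    t = np.clip(((yy - y0) * dy + (xx - x0) * dx) / L2, 0.0, 1.0)
    dist2 = (yy - (y0 + t * dy)) ** 2 + (xx - (x0 + t * dx)) ** 2
    return dist2 <= (thickness / 2.0) ** 2


def _branch_segments(rng, h, w, thickness):
    """Recursive branch skeleton rooted at the bottom centre."""
    segments = []

    def grow(p, angle, length, thick, depth):
        y0, x0 = p
        y1 = y0 - length * np.cos(angle)
        x1 = x0 + length * np.sin(angle)
        segments.append(((y0, x0), (y1, x1), thick))
        if depth == 0:
            return
        n_children = 2 if depth > 1 else int(rng.integers(1, 3))
        for _ in range(n_children):
            d_angle = rng.uniform(-0.8, 0.8)
            grow((y1, x1), angle + d_angle, length * rng.uniform(0.55, 0.75),
                 max(1.0, thick * 0.7), depth - 1)

    trunk_len = 0.45 * h
    grow((h - 1.0, w / 2.0), rng.uniform(-0.15, 0.15), trunk_len, thickness, depth=3)
    return segments


def generate_scene(spec: SceneSpec) -> SegScene:
    """Draw one scene; mask counts are exact (taken after compositing)."""
    spec.validate()
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((h, w), dtype=np.uint8)

    # z-order: branch first (lowest), then leaves, then flowers/fruits on top
    if spec.branch_thickness > 0:
        for p0, p1, thick in _branch_segments(rng, h, w, spec.branch_thickness):
            mask[_capsule_mask(h, w, p0, p1, thick)] = LABELS["branch"]

    if spec.leaf_coverage > 0:
        target = spec.leaf_coverage * h * w
        blob_a = max(4.0, 0.07 * min(h, w))
        max_blobs = 4000
        for _ in range(max_blobs):
            if (mask == LABELS["leaf"]).sum() >= target:
                break
            cy = rng.uniform(0.05 * h, 0.85 * h)
            cx = rng.uniform(0.08 * w, 0.92 * w)
            a = blob_a * rng.uniform(0.7, 1.5)
            b = a * rng.uniform(0.45, 0.8)
            theta = rng.uniform(0, np.pi)
            mask[_ellipse_mask(h, w, cy, cx, a, b, theta)] = LABELS["leaf"]

    organ_label = LABELS["flower"] if spec.stage == "flowering" else LABELS["fruit"]
    for _ in range(spec.n_flowers_or_fruits):
        cy = rng.uniform(0.08 * h, 0.75 * h)
        cx = rng.uniform(0.1 * w, 0.9 * w)
        r = max(2.0, spec.organ_radius * rng.uniform(0.75, 1.25))
        mask[_disc_mask(h, w, cy, cx, r)] = organ_label

    true_counts = np.bincount(mask.ravel(), minlength=5).astype(np.int64)

    # paint the image: per-class base colour + mild pixel noise
    image = np.empty((h, w, 3), dtype=np.float64)
    bg = float(spec.background_value)
    base = {
        0: (bg, bg, bg),
        1: PALETTE[1],
        2: PALETTE[2],
        3: PALETTE[3],
        4: PALETTE[4],
    }
    for label, colour in base.items():
        sel = mask == label
        image[sel] = colour
    noise_amp = np.where(mask == 0, 2.0, 8.0)
    image += rng.normal(0.0, 1.0, size=(h, w, 3)) * noise_amp[..., None]
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return SegScene(image=image, mask=mask, true_counts=true_counts, spec=spec)


# ---------------------------------------------------------------------------
# reflectance rasters
# ---------------------------------------------------------------------------

# Band means affine in vigor v in [0,1]: healthy canopies reflect more NIR
# and green and absorb more red/blue.
_BAND_MODEL = {
    "B": (0.10, -0.03),
    "G": (0.16, +0.10),
    "R": (0.30, -0.18),
    "NIR": (0.35, +0.45),
}
BAND_ORDER = ("B", "G", "R", "NIR")


def band_means(vigor: float) -> dict:
    """Analytic mean reflectance per band at latent vigor `vigor`."""
    return {name: a + slope * vigor for name, (a, slope) in _BAND_MODEL.items()}


def generate_reflectance(plot_truth: PlotTruth, width: int, height: int,
                         seed: int = 0, noise_sd: float = 0.02,
                         noise_corr_sigma: float = 3.0) -> np.ndarray:
    """4 x H x W reflectance raster (band order B, G, R, NIR) in [0, 1]."""
    if width <= 0 or height <= 0:
        raise ValueError("raster dimensions must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    means = band_means(plot_truth.latent_vigor)
    raster = np.empty((4, height, width), dtype=np.float64)
    for i, name in enumerate(BAND_ORDER):
        layer = np.full((height, width), means[name])
        if noise_sd > 0:
            white = rng.standard_normal((height, width))
            smooth = gaussian_filter(white, sigma=noise_corr_sigma)
            sd = smooth.std()
            if sd > 0:
                smooth = smooth / sd * noise_sd
            layer = layer + smooth
        raster[i] = layer
    return np.clip(raster, 0.0, 1.0)


# ---------------------------------------------------------------------------
# plot records
# ---------------------------------------------------------------------------

def _logistic(v, lo, span, steep=4.0):
    return lo + span / (1.0 + np.exp(-steep * (v - 0.5)))


def plot_indices_from_vigor(vigor: float) -> dict:
    """Noise-free vegetation-index values implied by the band model."""
    m = band_means(vigor)
    nir, r, g, b = m["NIR"], m["R"], m["G"], m["B"]
    total = r + g + b
    rn, gn, bn = r / total, g / total, b / total
    return {
        "d1": nir - r,                                     # DVI
        "d2": nir - g,                                     # GDVI
        "d3": 2.5 * (nir - g) / (nir + 6.0 * g - 7.5 * b + 1.0),  # GEVI
        "k1": (gn - rn) / (gn + rn - bn),                  # VARI
    }


def generate_plot_dataset(n_plots: int, beta=None, noise_sd: float = DEFAULT_NOISE_SD,
                          seed: int = 0, intercept: float = DEFAULT_INTERCEPT,
                          feature_noise: float = 1.0) -> list[PlotTruth]:
    """Sample plot records with yield = intercept + beta . x + N(0, noise_sd).

    `feature_noise` scales the measurement noise on every feature (0 gives
    noise-free features driven purely by latent vigor).
    """
    if n_plots < 2:
        raise ValueError("n_plots must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    beta = DEFAULT_BETA.copy() if beta is None else np.asarray(beta, dtype=np.float64)
    if beta.shape != (len(FEATURE_ORDER),):
        raise ValueError(f"beta must have length {len(FEATURE_ORDER)}")
    rng = np.random.default_rng(seed)
    plots = []
    for i in range(n_plots):
        v = rng.uniform(0.0, 1.0)
        fn = feature_noise
        s1 = 34.0 + 12.0 * v + rng.normal(0, 0.8 * fn)
        s2 = 32.0 + 13.0 * v + rng.normal(0, 0.8 * fn)
        f1 = float(np.clip(_logistic(v, 0.08, 0.22) + rng.normal(0, 0.010 * fn), 0, 1))
        f2 = float(max(0.0, _logistic(v, 0.15, 0.45) + rng.normal(0, 0.020 * fn)))
        f3 = float(np.clip(_logistic(v, 0.05, 0.20) + rng.normal(0, 0.010 * fn), 0, 1))
        f4 = float(max(0.0, _logistic(v, 0.10, 0.40) + rng.normal(0, 0.020 * fn)))
        idx = plot_indices_from_vigor(v)
        d1 = idx["d1"] + rng.normal(0, 0.010 * fn)
        d2 = idx["d2"] + rng.normal(0, 0.010 * fn)
        d3 = idx["d3"] + rng.normal(0, 0.010 * fn)
        k1 = idx["k1"] + rng.normal(0, 0.010 * fn)
        x = np.array([s1, s2, f1, f2, f3, f4, d1, d2, d3, k1])
        y = intercept + float(beta @ x)
        if noise_sd > 0:
            y += rng.normal(0, noise_sd)
        plots.append(PlotTruth(
            plot_id=f"plot_{i + 1:04d}", latent_vigor=float(v),
            s1=float(s1), s2=float(s2), f1=f1, f2=f2, f3=f3, f4=f4,
            d1=float(d1), d2=float(d2), d3=float(d3), k1=float(k1),
            yield_kg=float(y), beta=beta.copy(), intercept=intercept,
            noise_sd=noise_sd))
    return plots


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_scene(scene: SegScene, basepath) -> tuple:
    """Write `<base>.png` (image) and `<base>_mask.png` (indexed palette PNG)."""
    basepath = Path(basepath)
    img_path = basepath.with_suffix(".png")
    mask_path = basepath.parent / f"{basepath.stem}_mask.png"
    Image.fromarray(scene.image).save(img_path)
    pal_img = Image.fromarray(scene.mask, mode="P")
    flat = []
    for label in range(5):
        flat.extend(PALETTE[label])
    pal_img.putpalette(flat)
    pal_img.save(mask_path)
    return img_path, mask_path


def load_scene(basepath) -> SegScene:
    basepath = Path(basepath)
    image = np.asarray(Image.open(basepath.with_suffix(".png")).convert("RGB"))
    mask_path = basepath.parent / f"{basepath.stem}_mask.png"
    mask = np.asarray(Image.open(mask_path)).astype(np.uint8)
    counts = np.bincount(mask.ravel(), minlength=5).astype(np.int64)
    return SegScene(image=image, mask=mask, true_counts=counts)


def save_raster(raster: np.ndarray, path):
    """Write a 4-band float32 TIFF (band order B, G, R, NIR)."""
    import tifffile
    tifffile.imwrite(Path(path), np.asarray(raster, dtype=np.float32),
                     photometric="minisblack")


def load_raster(path) -> np.ndarray:
    import tifffile
    return np.asarray(tifffile.imread(Path(path)), dtype=np.float64)


def plots_to_frame(plots):
    import pandas as pd
    rows = [{"plot_id": p.plot_id, "s1": p.s1, "s2": p.s2,
             "f1": p.f1, "f2": p.f2, "f3": p.f3, "f4": p.f4,
             "yield_kg": p.yield_kg} for p in plots]
    return pd.DataFrame(rows)


def save_plot_table(plots, path, full: bool = False):
    """CSV with header plot_id,s1,s2,f1,f2,f3,f4,yield_kg (+ indices when full)."""
    import pandas as pd
    df = plots_to_frame(plots)
    if full:
        extra = pd.DataFrame([{"d1": p.d1, "d2": p.d2, "d3": p.d3, "k1": p.k1,
                               "latent_vigor": p.latent_vigor} for p in plots])
        df = pd.concat([df, extra], axis=1)
    df.to_csv(Path(path), index=False)
    return df


def save_generation_config(plots, path):
    """JSON sidecar recording beta, intercept and noise level."""
    if not plots:
        raise ValueError("no plots")
    p = plots[0]
    payload = {"beta": list(map(float, p.beta)), "intercept": p.intercept,
               "noise_sd": p.noise_sd, "feature_order": FEATURE_ORDER}
    Path(path).write_text(json.dumps(payload, indent=2))
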