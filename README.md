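# orchardfusion

Plot-level apple yield estimation for small orchard blocks, combining three
complementary views of a fruit tree:

* **structure** — flowers, fruits, leaves and branches segmented out of
  ground-based tree photographs by an attention-augmented DeepLabv3+
  network, summarised as four structural ratios;
* **spectrum** — visible and multispectral vegetation indices from 4-band
  (B, G, R, NIR) reflectance rasters, aggregated per plot polygon;
* **biochemistry** — leaf chlorophyll (SPAD) readings per phenological
  stage.

The fused per-plot feature record is fed to four regressors (KNN, PLS,
random forest, RBF-SVM) on a seeded 7:3 split, scored with R²/RMSE, and
explained with *exact* Shapley feature attribution (full coalition
enumeration, not an approximation). Because the original field imagery is
not publicly deposited, the package ships a synthetic-orchard generator
with exact ground truth, so every stage is testable end to end.

## The method in brief

**Segmentation.** A DeepLabv3+ encoder–decoder (small residual backbone,
output stride 16, ASPP context head) with two attention blocks: CBAM on the
backbone's final feature map (channel gate `σ(MLP(avg) + MLP(max))`
followed by a 7×7 spatial gate), and ECA on the low-level skip path just
before decoder concatenation (1-D channel convolution with adaptive kernel
size `k = odd(|log₂C/γ + b/γ|)`, so `k = 5` at `C = 256, γ = 2, b = 1`).
The network is trained with pixel-wise cross-entropy; everything runs on a
compact numpy autodiff engine bundled with the package, so no GPU framework
is needed.

**Structural ratios.** Masks are tiled (512 px in the field protocol),
background-only tiles dropped, per-class pixel counts pooled, then with
`SA = FA + IA + GA` (flower + leaf + trunk area, flowering stage) and
analogously `SB` for the young-fruit stage:

    f1 = FA/SA    f2 = FA/IA    f3 = FB/SB    f4 = FB/IB

**Vegetation indices.** Visible bands are first normalised to chromatic
coordinates `r = rt/(rt+gt+bt)` etc., making the six visible indices
(VARI, ExR, ExG, GLI, NDI, MGRVI) invariant to illumination scaling; the
six multispectral indices (DVI, GDVI, EVI, GEVI, NDVI, GNDVI) come straight
from reflectance. Per-plot values are means over valid pixels whose centres
fall inside the plot polygon.

**Fusion and evaluation.** Features are screened by per-group Pearson-|r|
rules and assembled into nested sets A (SPAD), B (ratios), C (screened
indices d1–d3, k1) and their unions D–G. Models are scored with
`R² = 1 − Σ(ŷ−y)²/Σ(ȳ−y)²` and `RMSE = √(Σ(y−ŷ)²/m)` (kg).

## Worked example

```python
from orchardfusion.synthetic import generate_plot_dataset
from orchardfusion.fusion import split_records, fit_and_predict, evaluate

plots = generate_plot_dataset(80, noise_sd=5.0, seed=7)   # 80 plots, 5 kg noise
train, test = split_records(plots, seed=7)                # 56 / 24
_, yhat, _ = fit_and_predict("SVM", train, test, "G", seed=7)
res = evaluate(test["yield_kg"], yhat)
print(f"SVM, fused set G: R2={res.r2:.3f} RMSE={res.rmse:.2f} kg")
```

prints

```
SVM, fused set G: R2=0.994 RMSE=5.65 kg
```

i.e. on synthetic plots whose yield is a known linear function of all ten
fused features plus 5 kg of noise, the grid-searched RBF-SVM recovers the
signal almost completely on the held-out 24 plots. The full pipeline is
also available from the shell:

```bash
orchardfusion run-all --config examples/demo_config.json
orchardfusion explain --config examples/demo_config.json   # Shapley report
```

which writes scenes, masks, rasters, per-plot tables, the feature-set ×
model × split R²/RMSE grid (`fusion_results.csv`) and a Shapley attribution
table (`shapley.csv`) under the configured output directory.

## Layout

| module | contents |
| --- | --- |
| `orchardfusion.nn` | minimal numpy reverse-mode autodiff, layers, SGD/Adam |
| `orchardfusion.segmentation` | CBAM, ECA, DeepLabv3+, training loop, PA/AccClass/IoU/mIoU |
| `orchardfusion.synthetic` | scene/raster/plot generators with exact ground truth |
| `orchardfusion.structure` | tiling, background filter, pixel counts, ratios f1–f4 |
| `orchardfusion.indices` | chromatic normalisation, 12 vegetation indices, zonal means |
| `orchardfusion.fusion` | screening, feature sets A–G, KNN/PLS/RF/SVM, R²/RMSE |
| `orchardfusion.shapley` | exact Shapley values by coalition enumeration |
| `orchardfusion.pipeline` / `cli` | staged orchestration and the `orchardfusion` command |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
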