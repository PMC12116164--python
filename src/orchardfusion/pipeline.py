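"""End-to-end orchestration: simulate -> segment -> extract -> fuse -> explain.

Each stage reads and writes the standard on-disk formats (paired PNGs,
multiband TIFF, GeoJSON, CSV, JSON), so stages can be re-run independently
from the CLI.  Given fixed seeds the whole run is reproducible: the report
JSON is byte-identical across runs except for the "timings" section.
"""

from __future__ import annotations

import json
import time
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import (FEATURE_ORDER, DEFAULT_BETA, DEFAULT_INTERCEPT,
                        DEFAULT_NOISE_SD, PlotTruth, SceneSpec, generate_plot_dataset,
                        generate_reflectance, generate_scene, load_scene,
                        save_generation_config, save_plot_table, save_raster,
                        load_raster, save_scene)
from .structure import (count_class_pixels, filter_background_tiles, mean_ratios,
                        structural_ratios, tile_image)
from .indices import (BandStack, INDEX_ALIASES, multispectral_indices,
                      normalize_rgb, visible_indices, zonal_index)
from .fusion import MODEL_NAMES, FEATURE_SETS, build_feature_matrix, evaluate_grid, fit_and_predict, split_records
from .shapley import shapley_importance

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "segtrain", "structure", "indices", "fuse", "explain")


@dataclass
class RunConfig:
    outdir: str = "orchardfusion_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # simulation
    n_plots: int = 80
    trees_per_plot: int = 3
    scene_size: int = 192
    organ_radius: float = 7.0
    leaf_coverage: float = 0.30
    branch_thickness: float = 5.0
    raster_size: tuple = (48, 64)
    beta: tuple = tuple(DEFAULT_BETA)
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = DEFAULT_NOISE_SD
    # segmentation
    use_true_masks: bool = True
    segtrain_scenes: int = 8
    segtrain_scene_size: int = 128
    segtrain_steps: int = 200
    model_config: dict = field(default_factory=dict)
    train_config: dict = field(default_factory=dict)
    # structure extraction
    tile_size: int = 64
    whiteness_threshold: int = 240
    min_foreground_fraction: float = 0.01
    # fusion
    feature_sets: tuple = ("A", "B", "C", "G")
    models: tuple = MODEL_NAMES
    explain_model: str = "SVM"
    explain_feature_set: str = "G"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def echo(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["beta"] = list(map(float, self.beta))
        d["raster_size"] = list(self.raster_size)
        d["feature_sets"] = list(self.feature_sets)
        d["models"] = list(self.models)
        return d


def validate_config(config: RunConfig) -> list:
    """Return (level, message) findings; empty list means runnable."""
    findings = []
    base = Path(config.outdir)
    for stage in config.stages:
        if stage not in ALL_STAGES:
            findings.append(("error", f"unknown stage {stage!r}"))
    if config.n_plots < 10 and "fuse" in config.stages:
        findings.append(("error", "fuse stage needs n_plots >= 10 for a 7:3 split"))
    for fs in config.feature_sets:
        if fs not in FEATURE_SETS:
            findings.append(("error", f"unknown feature set {fs!r}"))
    for m in config.models:
        if m.upper() not in MODEL_NAMES:
            findings.append(("error", f"unknown model {m!r}"))
    if "simulate" not in config.stages:
        # downstream stages must find their inputs on disk
        need = {"structure": ["scenes", "plots.csv"],
                "indices": ["rasters", "polygons.geojson"],
                "fuse": ["plots.csv"]}
        for stage, paths in need.items():
            if stage in config.stages:
                for rel in paths:
                    if not (base / rel).exists():
                        findings.append(("error",
                                         f"stage {stage!r} enabled but input "
                                         f"{base / rel} is missing"))
    tc = config.train_config
    if "segtrain" in config.stages and tc.get("epochs", 1) == 0:
        findings.append(("warning", "segtrain epochs=0: model will be untrained"))
    if config.explain_model.upper() not in MODEL_NAMES:
        findings.append(("error", f"unknown explain model {config.explain_model!r}"))
    return findings


def _child_seed(seed: int, *tags) -> int:
    # stable across processes (unlike hash()), bounded below 2**31
    h = seed & 0x7FFFFFFF
    for t in tags:
        h = (h * 1000003 + zlib.crc32(str(t).encode())) & 0x7FFFFFFF
    return h


def _scene_spec_for_plot(plot: PlotTruth, stage: str, tree: int,
                         config: RunConfig) -> SceneSpec:
    """Scene parameters realising (approximately) the plot's structural ratios."""
    size = config.scene_size
    leaf_px = config.leaf_coverage * size * size
    organ_px = np.pi * config.organ_radius ** 2
    ratio = plot.f2 if stage == "flowering" else plot.f4
    n_organs = max(1, int(round(ratio * leaf_px / organ_px)))
    return SceneSpec(width=size, height=size, stage=stage,
                     n_flowers_or_fruits=n_organs,
                     leaf_coverage=config.leaf_coverage,
                     branch_thickness=config.branch_thickness,
                     organ_radius=config.organ_radius,
                     seed=_child_seed(plot_seed(plot), stage, tree))


def plot_seed(plot: PlotTruth) -> int:
    return int(plot.plot_id.rsplit("_", 1)[-1])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    plots = generate_plot_dataset(config.n_plots, beta=np.asarray(config.beta),
                                  noise_sd=config.noise_sd, seed=config.seed,
                                  intercept=config.intercept)
    save_plot_table(plots, outdir / "plots.csv")
    save_plot_table(plots, outdir / "plots_full.csv", full=True)
    save_generation_config(plots, outdir / "generation.json")

    scenes_dir = outdir / "scenes"
    rasters_dir = outdir / "rasters"
    scenes_dir.mkdir(exist_ok=True)
    rasters_dir.mkdir(exist_ok=True)
    n_scenes = 0
    features = []
    rh, rw = config.raster_size
    for plot in plots:
        for stage in ("flowering", "young_fruit"):
            for tree in range(config.trees_per_plot):
                spec = _scene_spec_for_plot(plot, stage, tree, config)
                scene = generate_scene(spec)
                save_scene(scene, scenes_dir / f"{plot.plot_id}_{stage}_t{tree}")
                n_scenes += 1
        raster = generate_reflectance(plot, rw, rh,
                                      seed=_child_seed(config.seed, plot.plot_id))
        save_raster(raster, rasters_dir / f"{plot.plot_id}.tif")
        features.append({"type": "Feature",
                         "properties": {"plot_id": plot.plot_id},
                         "geometry": {"type": "Polygon", "coordinates": [[
                             [2, 2], [rw - 2, 2], [rw - 2, rh - 2], [2, rh - 2], [2, 2]]]}})
    (outdir / "polygons.geojson").write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=2))
    return {"plots": len(plots), "scenes": n_scenes, "rasters": len(plots)}


def stage_segtrain(config: RunConfig, outdir: Path) -> dict:
    from .segmentation import (ModelConfig, TrainConfig, build_model,
                               save_checkpoint, save_history, train)
    mc = ModelConfig(**{"input_size": config.segtrain_scene_size,
                        **config.model_config})
    tc_kwargs = {"epochs": 100, "batch_size": 4, "learning_rate": 0.01,
                 "optimizer": "adam", "val_fraction": 0.0,
                 "seed": _child_seed(config.seed, "segtrain"),
                 "max_steps": config.segtrain_steps}
    tc_kwargs.update(config.train_config)
    tc = TrainConfig(**tc_kwargs)
    size = config.segtrain_scene_size
    scenes = [generate_scene(SceneSpec(
        width=size, height=size,
        stage="flowering" if i % 2 == 0 else "young_fruit",
        seed=_child_seed(config.seed, "segtrain_scene", i)))
        for i in range(config.segtrain_scenes)]
    model = build_model(mc, seed=_child_seed(config.seed, "seg_init"))
    model, history = train(model, scenes, tc)
    save_checkpoint(model, outdir / "segmodel.ckpt")
    save_history(history, outdir / "history.csv")
    from .segmentation import evaluate_segmentation, predict_mask
    preds = [predict_mask(model, s.image) for s in scenes]
    metrics = evaluate_segmentation(preds, [s.mask for s in scenes], mc.n_classes)
    (outdir / "seg_metrics.json").write_text(json.dumps(metrics.to_dict(), indent=2))
    return {"scenes": len(scenes), "steps": len(history["train_loss"]),
            "final_train_loss": history["train_loss"][-1],
            "train_miou": metrics.miou, "train_pa": metrics.pixel_accuracy}


def stage_structure(config: RunConfig, outdir: Path) -> dict:
    scenes_dir = outdir / "scenes"
    plots_df = pd.read_csv(outdir / "plots.csv")
    model = None
    if not config.use_true_masks:
        from .segmentation import load_checkpoint, predict_mask
        model = load_checkpoint(outdir / "segmodel.ckpt")
    rows = []
    for plot_id in plots_df["plot_id"]:
        per_stage = {"flowering": [], "young_fruit": []}
        for stage in ("flowering", "young_fruit"):
            for tree in range(config.trees_per_plot):
                scene = load_scene(scenes_dir / f"{plot_id}_{stage}_t{tree}")
                if model is not None:
                    from .segmentation import predict_mask
                    mask = predict_mask(model, scene.image)
                else:
                    mask = scene.mask
                grid = tile_image(scene.image, mask, tile_size=config.tile_size)
                kept = filter_background_tiles(
                    grid, whiteness_threshold=config.whiteness_threshold,
                    min_foreground_fraction=config.min_foreground_fraction)
                counts = count_class_pixels(kept, stage)
                per_stage[stage].append(structural_ratios(counts))
        agg = mean_ratios(per_stage["flowering"] + per_stage["young_fruit"])
        rows.append({"plot_id": plot_id, "f1": agg.f1, "f2": agg.f2,
                     "f3": agg.f3, "f4": agg.f4})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "ratios.csv", index=False)
    return {"plots": len(df), "masks": "predicted" if model is not None else "ground_truth"}


def stage_indices(config: RunConfig, outdir: Path) -> dict:
    from shapely.geometry import shape as geo_shape
    geo = json.loads((outdir / "polygons.geojson").read_text())
    polys = {f["properties"]["plot_id"]: geo_shape(f["geometry"])
             for f in geo["features"]}
    rows = []
    for plot_id, poly in polys.items():
        raster = load_raster(outdir / "rasters" / f"{plot_id}.tif")
        stack = BandStack(bands={"B": raster[0], "G": raster[1],
                                 "R": raster[2], "NIR": raster[3]})
        vis = visible_indices(normalize_rgb(stack))
        mul = multispectral_indices(stack)
        row = {"plot_id": plot_id}
        for name, arr in {**vis, **mul}.items():
            value, _n = zonal_index(arr, poly, stack.transform)
            row[name] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "indices_full.csv", index=False)
    screened = df[["plot_id"]].copy()
    for raw, alias in INDEX_ALIASES.items():
        screened[alias] = df[raw]
    screened.to_csv(outdir / "indices.csv", index=False)
    return {"plots": len(df), "indices": [c for c in df.columns if c != "plot_id"]}


def _fused_records(outdir: Path) -> pd.DataFrame:
    plots = pd.read_csv(outdir / "plots.csv")[["plot_id", "s1", "s2", "yield_kg"]]
    ratios = pd.read_csv(outdir / "ratios.csv")
    idx = pd.read_csv(outdir / "indices.csv")
    df = plots.merge(ratios, on="plot_id").merge(idx, on="plot_id")
    return df


def stage_fuse(config: RunConfig, outdir: Path) -> dict:
    records = _fused_records(outdir)
    records.to_csv(outdir / "fused_records.csv", index=False)
    grid = evaluate_grid(records, feature_sets=config.feature_sets,
                         models=tuple(m.upper() for m in config.models),
                         seed=_child_seed(config.seed, "fuse"))
    grid.to_csv(outdir / "fusion_results.csv", index=False)
    (outdir / "fusion_results.json").write_text(
        grid.to_json(orient="records", indent=2))
    return {"records": len(records),
            "grid_cells": len(grid),
            "grid": grid.to_dict(orient="records")}


def stage_explain(config: RunConfig, outdir: Path) -> dict:
    records = _fused_records(outdir)
    seed = _child_seed(config.seed, "fuse")
    train_df, test_df = split_records(records, seed=seed)
    fs = config.explain_feature_set
    _, _, est = fit_and_predict(config.explain_model.upper(), train_df, test_df,
                                fs, seed=seed)
    X_train, _ = build_feature_matrix(train_df, fs)
    X_test, _ = build_feature_matrix(test_df, fs)
    names = FEATURE_SETS[fs]
    report = shapley_importance(est, X_test, X_train, feature_names=names)
    rows = []
    for i, plot_id in enumerate(test_df["plot_id"]):
        for j, name in enumerate(names):
            rows.append({"plot_id": plot_id, "feature": name,
                         "phi": report.phi[i, j]})
    pd.DataFrame(rows).to_csv(outdir / "shapley.csv", index=False)
    summary = {"baseline_kg": report.baseline,
               "global_importance_kg": report.global_importance(),
               "max_efficiency_gap": float(report.efficiency_gap().max())}
    (outdir / "shapley_summary.json").write_text(json.dumps(summary, indent=2))
    return {"explained": len(test_df), "model": config.explain_model.upper(),
            "feature_set": fs, **summary}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segtrain": stage_segtrain,
    "structure": stage_structure,
    "indices": stage_indices,
    "fuse": stage_fuse,
    "explain": stage_explain,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    findings = validate_config(config)
    errors = [msg for level, msg in findings if level == "error"]
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    for level, msg in findings:
        warnings.warn(msg)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": config.seed,
              "config": config.echo(), "stages": {}, "timings": {}}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["timings"][stage] = time.perf_counter() - t0
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
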