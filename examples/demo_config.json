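{
  "outdir": "orchardfusion_demo",
  "seed": 7,
  "stages": ["simulate", "structure", "indices", "fuse", "explain"],
  "n_plots": 20,
  "trees_per_plot": 2,
  "scene_size": 160,
  "raster_size": [32, 48],
  "tile_size": 64,
  "feature_sets": ["A", "B", "C", "G"],
  "models": ["KNN", "PLS", "RF", "SVM"],
  "explain_model": "SVM",
  "explain_feature_set": "G"
}
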