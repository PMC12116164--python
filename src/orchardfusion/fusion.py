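"""Multi-source feature fusion for plot-level yield estimation.

Per-plot records fuse three feature groups — SPAD chlorophyll readings
(s1, s2), structural ratios from segmentation masks (f1..f4), and screened
vegetation indices (d1 = DVI, d2 = GDVI, d3 = GEVI, k1 = VARI) — into the
nested feature sets A..G.  Four regressors (KNN, PLS, RF, SVM) are fitted
on a seeded 7:3 split and scored with

    R^2  = 1 - sum (yhat - y)^2 / sum (ybar - y)^2
    RMSE = sqrt( sum (y - yhat)^2 / m )

Feature screening follows per-group Pearson-|r| rules with an explicit
include/exclude override, because a bare threshold does not uniquely
reproduce the canonical ten-feature fused set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_SETS", "FUSED_FEATURES", "FEATURE_GROUPS", "DEFAULT_SCREEN_RULES",
    "PlotRecord", "EvalResult",
    "aggregate_spad", "compute_plot_yield", "pearson", "correlation_table",
    "select_features", "build_feature_matrix", "split_records",
    "fit_and_predict", "evaluate", "evaluate_grid",
]

# Nested feature sets: SPAD (A), structural ratios (B), screened indices (C)
# and their unions.
FEATURE_SETS = {
    "A": ["s1", "s2"],
    "B": ["f1", "f2", "f3", "f4"],
    "C": ["d1", "d2", "d3", "k1"],
}
FEATURE_SETS["D"] = FEATURE_SETS["A"] + FEATURE_SETS["B"]
FEATURE_SETS["E"] = FEATURE_SETS["B"] + FEATURE_SETS["C"]
FEATURE_SETS["F"] = FEATURE_SETS["A"] + FEATURE_SETS["C"]
FEATURE_SETS["G"] = FEATURE_SETS["A"] + FEATURE_SETS["B"] + FEATURE_SETS["C"]
FUSED_FEATURES = FEATURE_SETS["G"]

MODEL_NAMES = ("KNN", "PLS", "RF", "SVM")

# feature name -> screening group
FEATURE_GROUPS = {
    "s1": "spad", "s2": "spad",
    "f1": "structural", "f2": "structural", "f3": "structural", "f4": "structural",
    "VARI": "visible", "ExR": "visible", "EXR": "visible", "ExG": "visible",
    "EXG": "visible", "GLI": "visible", "NDI": "visible", "MGRVI": "visible",
    "ExGR": "visible", "EXGR": "visible", "RGBVI": "visible",
    "DVI": "multispectral", "GDVI": "multispectral", "EVI": "multispectral",
    "GEVI": "multispectral", "NDVI": "multispectral", "GNDVI": "multispectral",
    "GRVI": "multispectral", "RVI": "multispectral",
}

_SCREEN_ALIASES = {"DVI": "d1", "GDVI": "d2", "GEVI": "d3", "VARI": "k1"}

# Per-group rules: SPAD and multispectral pass at |r| > 0.6, structural at
# |r| > 0.7, and only the single best visible index is taken.  GNDVI is
# excluded explicitly: it clears the multispectral threshold yet is absent
# from the canonical fused set, so the screening rule alone would not
# reproduce that set (documented override, not guessed intent).
DEFAULT_SCREEN_RULES = {
    "spad": {"threshold": 0.6},
    "structural": {"threshold": 0.7},
    "multispectral": {"threshold": 0.6, "exclude": ["GNDVI"]},
    "visible": {"top_k": 1},
}

_CANONICAL_ORDER = ["s1", "s2", "f1", "f2", "f3", "f4", "d1", "d2", "d3", "k1"]


@dataclass
class PlotRecord:
    plot_id: str
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
    extra_indices: dict = field(default_factory=dict)


@dataclass
class EvalResult:
    model: str
    feature_set: str
    split: str
    r2: float
    rmse: float
    m: int


# ---------------------------------------------------------------------------
# field aggregation arithmetic
# ---------------------------------------------------------------------------

def aggregate_spad(per_tree_leaf_values) -> float:
    """Plot SPAD: mean over trees of the per-tree mean of six leaf readings."""
    trees = [np.asarray(t, dtype=np.float64) for t in per_tree_leaf_values]
    if not trees:
        raise ValueError("need at least one tree")
    for t in trees:
        if t.shape != (6,):
            raise ValueError(f"each tree needs exactly six leaf readings, got {t.shape}")
    return float(np.mean([t.mean() for t in trees]))


def compute_plot_yield(avg_fruit_count: float, avg_fruit_weight_kg: float,
                       n_trees: int = 20) -> float:
    """Plot yield: per-tree yield (count x unit weight) scaled to the plot."""
    if avg_fruit_count < 0 or avg_fruit_weight_kg < 0 or n_trees < 0:
        raise ValueError("inputs must be non-negative")
    return float(avg_fruit_count * avg_fruit_weight_kg * n_trees)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def pearson(x, y) -> float:
    """Sample Pearson correlation; raises on degenerate input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    from scipy.stats import pearsonr
    return float(pearsonr(x, y).statistic)


def correlation_table(records, feature_names=None) -> dict:
    """Pearson r of each feature against yield over the given records."""
    df = _records_frame(records)
    feature_names = feature_names or [c for c in df.columns
                                      if c not in ("plot_id", "yield_kg")]
    return {name: pearson(df[name].to_numpy(), df["yield_kg"].to_numpy())
            for name in feature_names}


def select_features(corr: dict, rules: dict | None = None) -> list:
    """Screen features by per-group |r| rules; returns model-input names.

    Screened index names are rewritten to their model aliases
    (DVI->d1, GDVI->d2, GEVI->d3, VARI->k1) and the result is ordered
    SPAD, structural, multispectral, visible.
    """
    if not corr:
        raise ValueError("empty correlation table")
    rules = DEFAULT_SCREEN_RULES if rules is None else rules
    grouped: dict[str, list] = {}
    for name, r in corr.items():
        group = FEATURE_GROUPS.get(name)
        if group is None:
            raise KeyError(f"feature {name!r} belongs to no known screening group")
        grouped.setdefault(group, []).append((name, r))

    chosen = []
    for group, members in grouped.items():
        rule = rules.get(group, {})
        excluded = set(rule.get("exclude", ()))
        included = set(rule.get("include", ()))
        members = [(n, r) for n, r in members if n not in excluded]
        if "top_k" in rule:
            members.sort(key=lambda nr: abs(nr[1]), reverse=True)
            picked = [n for n, _ in members[:rule["top_k"]]]
        else:
            thr = rule.get("threshold", 0.0)
            picked = [n for n, r in members if abs(r) > thr or thr == 0.0]
        picked += [n for n in included if n not in picked and n in dict(members)]
        chosen.extend(picked)

    aliased = [_SCREEN_ALIASES.get(n, n) for n in chosen]
    order = {n: i for i, n in enumerate(_CANONICAL_ORDER)}
    return sorted(aliased, key=lambda n: order.get(n, len(order)))


# ---------------------------------------------------------------------------
# matrices, splits, models
# ---------------------------------------------------------------------------

def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            rows.append(rec)
        else:
            row = {k: getattr(rec, k) for k in
                   ("plot_id", "s1", "s2", "f1", "f2", "f3", "f4",
                    "d1", "d2", "d3", "k1", "yield_kg") if hasattr(rec, k)}
            rows.append(row)
    return pd.DataFrame(rows)


def build_feature_matrix(records, feature_set) -> tuple:
    """(X, y) with columns ordered per the feature-set spec."""
    columns = FEATURE_SETS[feature_set] if isinstance(feature_set, str) else list(feature_set)
    df = _records_frame(records)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KeyError(f"records lack feature columns: {missing}")
    X = df[columns].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    y = df["yield_kg"].to_numpy(dtype=np.float64)
    return X, y


def split_records(records, ratio=(7, 3), seed: int = 0) -> tuple:
    """Seeded shuffle split; train size is round-half-up of the train share."""
    df = _records_frame(records).reset_index(drop=True)
    m = len(df)
    if m < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    frac = ratio[0] / sum(ratio)
    n_train = int(np.floor(frac * m + 0.5))
    train = df.iloc[order[:n_train]].reset_index(drop=True)
    test = df.iloc[order[n_train:]].reset_index(drop=True)
    return train, test


def _make_estimator(model_name: str, n_features: int, n_train: int,
                    hyperparams: dict | None, seed: int):
    from sklearn.model_selection import GridSearchCV, KFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    hp = dict(hyperparams or {})
    name = model_name.upper()
    cv = KFold(n_splits=min(5, n_train), shuffle=True, random_state=seed)

    if name == "KNN":
        from sklearn.neighbors import KNeighborsRegressor
        k = hp.pop("n_neighbors", 5)
        if k > n_train:
            raise ValueError(f"KNN needs n_neighbors <= training size ({k} > {n_train})")
        est = KNeighborsRegressor(n_neighbors=k, **hp)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if name == "PLS":
        from sklearn.cross_decomposition import PLSRegression
        if "n_components" in hp:
            est = PLSRegression(n_components=hp.pop("n_components"), **hp)
            return Pipeline([("scale", StandardScaler()), ("model", est)])
        max_comp = min(n_features, 5, n_train - 1)
        grid = {"model__n_components": list(range(1, max_comp + 1))}
        pipe = Pipeline([("scale", StandardScaler()), ("model", PLSRegression())])
        return GridSearchCV(pipe, grid, cv=cv, scoring="neg_mean_squared_error")
    if name == "RF":
        from sklearn.ensemble import RandomForestRegressor
        hp.setdefault("n_estimators", 500)
        return RandomForestRegressor(random_state=seed, **hp)
    if name == "SVM":
        from sklearn.svm import SVR
        if hp:
            return Pipeline([("scale", StandardScaler()), ("model", SVR(kernel="rbf", **hp))])
        grid = {"model__C": [1.0, 10.0, 100.0, 1000.0],
                "model__gamma": ["scale", 0.01, 0.1, 1.0],
                "model__epsilon": [0.01, 0.1]}
        pipe = Pipeline([("scale", StandardScaler()), ("model", SVR(kernel="rbf"))])
        return GridSearchCV(pipe, grid, cv=cv, scoring="neg_mean_squared_error")
    raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")


def fit_and_predict(model_name: str, train, test, feature_set="G",
                    hyperparams: dict | None = None, seed: int = 0):
    """Fit one regressor; returns (yhat_train, yhat_test, fitted_estimator)."""
    X_train, y_train = build_feature_matrix(train, feature_set)
    X_test, y_test = build_feature_matrix(test, feature_set)
    est = _make_estimator(model_name, X_train.shape[1], len(y_train), hyperparams, seed)
    est.fit(X_train, y_train)
    yhat_train = np.asarray(est.predict(X_train)).ravel()
    yhat_test = np.asarray(est.predict(X_test)).ravel()
    return yhat_train, yhat_test, est


def evaluate(y, yhat, model: str = "", feature_set: str = "",
             split: str = "") -> EvalResult:
    """R^2 and RMSE (kg) of predictions against true yields."""
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("y and yhat must be equal-length nonempty vectors")
    ss_tot = float(np.sum((y.mean() - y) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: zero target variance")
    ss_res = float(np.sum((yhat - y) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return EvalResult(model=model, feature_set=feature_set, split=split,
                      r2=r2, rmse=rmse, m=int(y.size))


def evaluate_grid(records, feature_sets=("A", "B", "C", "G"),
                  models=MODEL_NAMES, seed: int = 0,
                  hyperparams: dict | None = None) -> pd.DataFrame:
    """Feature-set x model x split grid of R^2/RMSE on one seeded 7:3 split."""
    train, test = split_records(records, seed=seed)
    rows = []
    for fs in feature_sets:
        for model_name in models:
            hp = (hyperparams or {}).get(model_name)
            yhat_tr, yhat_te, _ = fit_and_predict(model_name, train, test, fs,
                                                  hyperparams=hp, seed=seed)
            for split, frame, yhat in (("train", train, yhat_tr),
                                       ("test", test, yhat_te)):
                res = evaluate(frame["yield_kg"].to_numpy(), yhat,
                               model=model_name, feature_set=fs, split=split)
                rows.append({"feature_set": fs, "model": model_name,
                             "split": split, "R2": res.r2, "RMSE": res.rmse,
                             "m": res.m})
    return pd.DataFrame(rows)
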