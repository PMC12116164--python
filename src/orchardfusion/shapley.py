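"""Exact Shapley feature attribution by coalition enumeration.

For a fitted model f, explanation row x and background set Z, the value of
a coalition S is

    v(S) = mean over z in Z of f(x_S combined with z_{not S})

and the attribution of feature j is the Shapley value

    phi_j(x) = sum over S not containing j of
               |S|! (p - |S| - 1)! / p!  *  [ v(S + {j}) - v(S) ].

With p features all 2^p coalitions are enumerated, so efficiency
(sum_j phi_j = f(x) - v(empty)) holds to floating-point accuracy and the
values serve as a gold standard for any approximation.  Enumeration is
limited to p <= 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np

__all__ = ["ShapleyReport", "exact_shapley", "shapley_importance"]

MAX_EXACT_FEATURES = 15


@dataclass
class ShapleyReport:
    phi: np.ndarray                  # (n_explain, p) per-sample attributions
    baseline: float                  # expected prediction over the background
    feature_names: list = field(default_factory=list)
    predictions: np.ndarray | None = None

    def global_importance(self) -> dict:
        """Mean |phi| per feature, sorted descending."""
        imp = np.abs(self.phi).mean(axis=0)
        names = self.feature_names or [f"x{j}" for j in range(self.phi.shape[1])]
        pairs = sorted(zip(names, imp), key=lambda kv: kv[1], reverse=True)
        return {k: float(v) for k, v in pairs}

    def efficiency_gap(self) -> np.ndarray:
        """Per-sample |sum_j phi_j - (f(x) - baseline)|."""
        if self.predictions is None:
            raise ValueError("report carries no predictions")
        return np.abs(self.phi.sum(axis=1) - (self.predictions - self.baseline))


def exact_shapley(predict_fn, X_explain, X_background,
                  feature_names=None) -> ShapleyReport:
    """Exact Shapley values for every row of X_explain.

    predict_fn maps an (n, p) array to n predictions.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=np.float64))
    X_background = np.atleast_2d(np.asarray(X_background, dtype=np.float64))
    n, p = X_explain.shape
    m = X_background.shape[0]
    if X_background.shape[1] != p:
        raise ValueError("explain/background feature counts differ")
    if p > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration limited to {MAX_EXACT_FEATURES} features (got {p}); "
            "use a sampling approximation instead")

    n_coal = 1 << p
    # v[i, S]: coalition value for explanation row i and bitmask S
    v = np.empty((n, n_coal), dtype=np.float64)
    for s_mask in range(n_coal):
        members = [j for j in range(p) if s_mask >> j & 1]
        hybrid = np.repeat(X_background[None, :, :], n, axis=0)   # (n, m, p)
        if members:
            hybrid[:, :, members] = X_explain[:, None, members]
        preds = np.asarray(predict_fn(hybrid.reshape(n * m, p))).reshape(n, m)
        v[:, s_mask] = preds.mean(axis=1)

    weights = np.array([factorial(s) * factorial(p - s - 1) / factorial(p)
                        for s in range(p)])
    phi = np.zeros((n, p))
    sizes = np.array([bin(s).count("1") for s in range(n_coal)])
    for j in range(p):
        bit = 1 << j
        without = np.array([s for s in range(n_coal) if not s & bit])
        phi[:, j] = np.sum(weights[sizes[without]][None, :]
                           * (v[:, without | bit] - v[:, without]), axis=1)

    baseline = float(v[0, 0])
    predictions = np.asarray(predict_fn(X_explain)).ravel()
    return ShapleyReport(phi=phi, baseline=baseline,
                         feature_names=list(feature_names or []),
                         predictions=predictions)


def shapley_importance(model, X_explain, X_background,
                       feature_names=None) -> ShapleyReport:
    """Exact Shapley report for a fitted sklearn-style estimator."""
    return exact_shapley(lambda X: model.predict(X), X_explain, X_background,
                         feature_names=feature_names)
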