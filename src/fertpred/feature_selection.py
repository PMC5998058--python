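"""Multi-algorithm feature-weight fusion selection.

Nine feature-weighting algorithms score every feature on a min-max
normalized [0, 1] scale per algorithm.  A feature is *important* for one
benchmark replicate when its score is strictly above a threshold (default
0.5) under at least ``min_algorithms`` (default 5) of the algorithms; the
optimal feature set is the intersection of the important sets over the five
general benchmark replicates.

Entropy-family weights (chi-squared, information gain, gain ratio, gini,
symmetric uncertainty) discretize each continuous feature into 10
equal-width bins.  Relief is a ReliefF with k=10 neighbors; PCA weight is
the absolute loading on the first principal component; the SVM weight is
|w| of a linear SVM; deviation is the per-feature standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.svm import SVC

__all__ = [
    "ALGORITHMS",
    "FeatureWeightMatrix",
    "SelectionResult",
    "weight_features",
    "compute_weight_matrix",
    "fuse_and_select",
    "important_features",
    "retrain_on_selected",
]

ALGORITHMS = (
    "chi_squared",
    "info_gain",
    "gain_ratio",
    "gini",
    "deviation",
    "symmetric_uncertainty",
    "relief",
    "pca",
    "svm_weight",
)

_N_BINS = 10


def _minmax_row(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.zeros_like(w)
    return (w - lo) / (hi - lo)


def _discretize(x: np.ndarray, n_bins: int = _N_BINS) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _contingency(xb: np.ndarray, y: np.ndarray) -> np.ndarray:
    n_bins = xb.max() + 1
    classes = np.unique(y)
    table = np.zeros((n_bins, len(classes)))
    for j, c in enumerate(classes):
        table[:, j] = np.bincount(xb[y == c], minlength=n_bins)
    return table


def _chi2_stat(xb: np.ndarray, y: np.ndarray) -> float:
    obs = _contingency(xb, y)
    obs = obs[obs.sum(axis=1) > 0]
    if obs.shape[0] < 2:
        return 0.0
    exp = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def _info_gain(xb: np.ndarray, y: np.ndarray) -> float:
    table = _contingency(xb, y)
    h_y = _entropy(table.sum(axis=0))
    n = table.sum()
    h_cond = sum(
        (row.sum() / n) * _entropy(row) for row in table if row.sum() > 0
    )
    return h_y - h_cond


def _gini_gain(xb: np.ndarray, y: np.ndarray) -> float:
    table = _contingency(xb, y)
    n = table.sum()

    def gini(counts: np.ndarray) -> float:
        tot = counts.sum()
        if tot == 0:
            return 0.0
        p = counts / tot
        return 1.0 - float((p ** 2).sum())

    g_y = gini(table.sum(axis=0))
    g_cond = sum((row.sum() / n) * gini(row) for row in table)
    return g_y - g_cond


def _relief_weights(X: np.ndarray, y: np.ndarray, k: int = 10,
                    seed: int = 0) -> np.ndarray:
    # ReliefF over min-max scaled features (ranges then equal 1, so diffs
    # are already normalized).
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    Z = (X - lo) / rng
    n = len(Z)
    D = cdist(Z, Z)
    np.fill_diagonal(D, np.inf)
    W = np.zeros(Z.shape[1])
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        diff = np.flatnonzero(y != y[i])
        kh = min(k, len(same))
        km = min(k, len(diff))
        if kh == 0 or km == 0:
            continue
        hits = same[np.argsort(D[i, same])[:kh]]
        misses = diff[np.argsort(D[i, diff])[:km]]
        W += np.abs(Z[misses] - Z[i]).mean(axis=0) - np.abs(Z[hits] - Z[i]).mean(axis=0)
    return W / n


def weight_features(
    features: np.ndarray,
    labels: np.ndarray,
    algorithm: str,
    seed: int = 0,
) -> np.ndarray:
    """Score every feature under one weighting algorithm, min-max normalized.

    Constant features always receive weight 0.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; valid: {', '.join(ALGORITHMS)}"
        )
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    d = X.shape[1]
    constant = X.max(axis=0) == X.min(axis=0)

    if algorithm == "deviation":
        w = X.std(axis=0)
    elif algorithm == "pca":
        pca = PCA(n_components=1, random_state=seed)
        pca.fit(X)
        w = np.abs(pca.components_[0])
    elif algorithm == "svm_weight":
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        rng[rng == 0] = 1.0
        clf = SVC(kernel="linear", C=1.0, random_state=seed)
        clf.fit((X - lo) / rng, y)
        w = np.abs(clf.coef_.ravel())
    elif algorithm == "relief":
        w = _relief_weights(X, y, k=10, seed=seed)
    else:
        stat = {
            "chi_squared": _chi2_stat,
            "info_gain": _info_gain,
            "gain_ratio": None,
            "gini": _gini_gain,
            "symmetric_uncertainty": None,
        }[algorithm]
        w = np.zeros(d)
        h_y = _entropy(np.bincount(y))
        for j in range(d):
            if constant[j]:
                continue
            xb = _discretize(X[:, j])
            if algorithm == "gain_ratio":
                ig = _info_gain(xb, y)
                h_x = _entropy(np.bincount(xb))
                w[j] = ig / h_x if h_x > 0 else 0.0
            elif algorithm == "symmetric_uncertainty":
                ig = _info_gain(xb, y)
                h_x = _entropy(np.bincount(xb))
                w[j] = 2.0 * ig / (h_x + h_y) if (h_x + h_y) > 0 else 0.0
            else:
                w[j] = stat(xb, y)
    w = _minmax_row(np.asarray(w, dtype=float))
    # uninformative constant features are pinned to 0 even when the raw
    # score scale (e.g. relief) would place them mid-range after shifting
    w[constant] = 0.0
    return w


@dataclass
class FeatureWeightMatrix:
    """Per-algorithm normalized weight rows over a shared feature list."""

    algorithms: list[str]
    features: list[str]
    weights: np.ndarray  # (n_algorithms, n_features), each row in [0, 1]

    def important(self, score_threshold: float = 0.5,
                  min_algorithms: int = 5) -> set[str]:
        votes = (self.weights > score_threshold).sum(axis=0)
        return {f for f, v in zip(self.features, votes) if v >= min_algorithms}


def compute_weight_matrix(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str],
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
) -> FeatureWeightMatrix:
    """Run every weighting algorithm over one dataset."""
    rows = [weight_features(features, labels, alg, seed=seed) for alg in algorithms]
    return FeatureWeightMatrix(
        algorithms=list(algorithms),
        features=list(feature_names),
        weights=np.stack(rows),
    )


def important_features(matrix: FeatureWeightMatrix,
                       score_threshold: float = 0.5,
                       min_algorithms: int = 5) -> set[str]:
    return matrix.important(score_threshold, min_algorithms)


@dataclass
class SelectionResult:
    per_dataset_important: dict[int, set[str]]
    optimal_set: set[str]


def fuse_and_select(
    replicate_matrices: Mapping[int, FeatureWeightMatrix] | Sequence[FeatureWeightMatrix],
    score_threshold: float = 0.5,
    min_algorithms: int = 5,
) -> SelectionResult:
    """Intersect per-replicate important sets into the optimal feature set."""
    if not isinstance(replicate_matrices, Mapping):
        replicate_matrices = {i + 1: m for i, m in enumerate(replicate_matrices)}
    feature_space = None
    per_ds: dict[int, set[str]] = {}
    for rep, m in replicate_matrices.items():
        if feature_space is None:
            feature_space = m.features
        elif m.features != feature_space:
            raise ValueError("replicates must share the same feature space")
        per_ds[rep] = m.important(score_threshold, min_algorithms)
    optimal = set.intersection(*per_ds.values()) if per_ds else set()
    return SelectionResult(per_dataset_important=per_ds, optimal_set=optimal)


def retrain_on_selected(ds, selected, C_grid=None, gamma_grid=None, seed: int = 0,
                        cfg=None, cache=None):
    """Retrain a binary SVM restricted to the selected feature names."""
    from .classifier import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, train_binary
    from .descriptors import DescriptorConfig

    if not selected:
        raise ValueError("selected feature set must be non-empty")
    return train_binary(
        ds,
        cfg or DescriptorConfig(),
        C_grid or DEFAULT_C_GRID,
        gamma_grid or DEFAULT_GAMMA_GRID,
        seed=seed,
        feature_subset=sorted(selected),
        cache=cache,
    )
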