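"""RBF-SVM training with grid search and the two-layer architecture.

Layer 1 is a binary SVM separating fertility-related proteins from
non-fertility proteins, trained on the general (union) benchmark dataset.
Layer 2 holds three binary SVMs (oogenesis, spermatogenesis, embryogenesis,
each vs its own negative subsample); a sequence passed by layer 1 is
assigned the class with the highest calibrated probability.

Hyperparameters (cost C and RBF width gamma) are tuned by exhaustive grid
search under stratified five-fold cross-validation on the training split.
Features are min-max scaled to [0, 1] with statistics fitted on the
training split only and stored with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset_builder import BenchmarkDataset
from .descriptors import DescriptorConfig, extract_all, feature_names
from .evaluation import ConfusionCounts, MetricSet, compute_metrics, counts_from_predictions
from .sequence_io import ProteinSequence, validate_and_filter

__all__ = [
    "SvmParams",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "CVResult",
    "TrainedBinaryModel",
    "TwoLayerModel",
    "PredictionResult",
    "cross_validate",
    "grid_search",
    "train_binary",
    "train_two_layer",
    "predict_two_layer",
]

#: Default grids; they bracket the optima typically reported for this task
#: (C = 100, gamma between 0.001 and 0.09).
DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_GAMMA_GRID: tuple[float, ...] = (
    0.001, 0.002, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.08, 0.1,
)

#: Fixed alphabetical class order used for layer-2 tie-breaks.
CLASS_ORDER = ("embryogenesis", "oogenesis", "spermatogenesis")


@dataclass(frozen=True)
class SvmParams:
    """RBF-SVM hyperparameters: cost C and kernel width gamma.

    Some published tables print the kernel width under the symbol lambda;
    here it is always called gamma.
    """

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class CVResult:
    fold_metrics: list[MetricSet]
    pooled_counts: ConfusionCounts
    accuracy: float  # pooled over folds


class _MinMaxScaler:
    """Per-feature min-max scaling to [0,1]; constant features map to 0."""

    def __init__(self, X: np.ndarray):
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        rng[rng == 0] = 1.0
        self.range_ = rng

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.min_) / self.range_


def _fit_svc(X: np.ndarray, y: np.ndarray, params: SvmParams, seed: int,
             probability: bool = False):
    svc = SVC(C=params.C, gamma=params.gamma, kernel="rbf", random_state=seed)
    if probability:
        # Platt-style sigmoid calibration on internal stratified folds.
        clf = CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    else:
        clf = svc
    clf.fit(X, y)
    return clf


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    params: SvmParams,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation; counts pooled over folds.

    Scaling is refitted inside each fold on the fold-training part only, so
    no test information leaks into the scaler.
    """
    y = np.asarray(labels).astype(int)
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    fold_metrics = []
    for train_idx, test_idx in skf.split(features, y):
        scaler = _MinMaxScaler(features[train_idx])
        clf = _fit_svc(scaler.transform(features[train_idx]), y[train_idx], params, seed)
        pred = clf.predict(scaler.transform(features[test_idx]))
        counts = counts_from_predictions(y[test_idx], pred)
        fold_metrics.append(compute_metrics(counts))
        pooled = pooled + counts
    acc = compute_metrics(pooled).acc
    return CVResult(fold_metrics=fold_metrics, pooled_counts=pooled, accuracy=acc)


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 5,
    seed: int = 0,
) -> tuple[SvmParams, float, list[tuple[SvmParams, float]]]:
    """Exhaustive (C, gamma) search by CV accuracy.

    Returns the winning parameters, their CV accuracy, and the full table.
    Ties go to the smallest C, then the smallest gamma.
    """
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    table: list[tuple[SvmParams, float]] = []
    best: tuple[float, float, float] | None = None  # (-acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            params = SvmParams(C=C, gamma=gamma)
            acc = cross_validate(features, labels, params, k=k, seed=seed).accuracy
            table.append((params, acc))
            cand = (-acc, C, gamma)
            if best is None or cand < best:
                best = cand
    assert best is not None
    return SvmParams(C=best[1], gamma=best[2]), -best[0], table


@dataclass
class TrainedBinaryModel:
    """A fitted binary RBF-SVM plus everything needed to reapply it."""

    params: SvmParams
    clf: object  # fitted CalibratedClassifierCV over an RBF SVC
    scaler: _MinMaxScaler
    feature_indices: np.ndarray | None  # None = all features
    descriptor_fingerprint: str
    cv_accuracy: float
    class_label: str = ""

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if self.feature_indices is not None:
            X = X[:, self.feature_indices]
        return self.scaler.transform(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(self._prepare(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Calibrated probability of the positive class (label 1)."""
        pos_col = list(self.clf.classes_).index(1)
        return self.clf.predict_proba(self._prepare(X))[:, pos_col]

    @property
    def n_features(self) -> int:
        return int(self.clf.n_features_in_)


class FeatureCache:
    """Memoizes descriptor vectors by sequence id within one run."""

    def __init__(self, cfg: DescriptorConfig):
        self.cfg = cfg
        self._store: dict[str, np.ndarray] = {}

    def matrix(self, seqs: Iterable[ProteinSequence]) -> np.ndarray:
        rows = []
        for s in seqs:
            if s.id not in self._store:
                self._store[s.id] = extract_all(s, self.cfg).values
            rows.append(self._store[s.id])
        return np.stack(rows)


def _dataset_xy(ds: BenchmarkDataset, ids: set[str], cache: FeatureCache):
    seqs = ds.members(ids)
    label_of = ds.label_of
    X = cache.matrix(seqs)
    y = np.array([label_of[s.id] for s in seqs], dtype=int)
    return X, y


def train_binary(
    ds: BenchmarkDataset,
    cfg: DescriptorConfig = DescriptorConfig(),
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
    cache: FeatureCache | None = None,
) -> TrainedBinaryModel:
    """Train one binary SVM on a split benchmark dataset.

    Features are extracted for the training split, optionally restricted to
    ``feature_subset`` (names), min-max scaled (train statistics only),
    grid-searched, and the winner refitted on the full training split with
    probability calibration enabled.
    """
    if not ds.train_ids:
        raise ValueError("dataset has no train/test split; call split_train_test first")
    cache = cache or FeatureCache(cfg)
    X, y = _dataset_xy(ds, ds.train_ids, cache)
    indices: np.ndarray | None = None
    if feature_subset is not None:
        names = feature_names(cfg)
        pos = {n: i for i, n in enumerate(names)}
        missing = [n for n in feature_subset if n not in pos]
        if missing:
            raise ValueError(f"unknown feature names: {missing[:5]}")
        if len(feature_subset) == 0:
            raise ValueError("feature_subset must be non-empty")
        indices = np.array(sorted(pos[n] for n in feature_subset), dtype=int)
        X = X[:, indices]
    params, cv_acc, _ = grid_search(X, y, C_grid, gamma_grid, seed=seed)
    scaler = _MinMaxScaler(X)
    clf = _fit_svc(scaler.transform(X), y, params, seed, probability=True)
    return TrainedBinaryModel(
        params=params, clf=clf, scaler=scaler, feature_indices=indices,
        descriptor_fingerprint=cfg.fingerprint(), cv_accuracy=cv_acc,
        class_label=ds.class_label,
    )


def evaluate_on_test(model: TrainedBinaryModel, ds: BenchmarkDataset,
                     cache: FeatureCache) -> MetricSet:
    """Metrics of a trained model on the held-out test split of its dataset."""
    X, y = _dataset_xy(ds, ds.test_ids, cache)
    pred = model.predict(X)
    return compute_metrics(counts_from_predictions(y, pred))


@dataclass
class TwoLayerModel:
    """Layer-1 fertility detector + three layer-2 class discriminators."""

    layer1: TrainedBinaryModel
    layer2: Mapping[str, TrainedBinaryModel]
    threshold: float = 0.5
    descriptor_config: DescriptorConfig = field(default_factory=DescriptorConfig)

    def __post_init__(self) -> None:
        fps = {self.layer1.descriptor_fingerprint}
        fps |= {m.descriptor_fingerprint for m in self.layer2.values()}
        if len(fps) != 1 or self.descriptor_config.fingerprint() not in fps:
            raise ValueError("all member models must share one descriptor configuration")


@dataclass
class PredictionResult:
    sequence_id: str
    layer1_probability: float
    is_fertility: bool
    class_scores: dict[str, float] | None
    assigned_class: str | None
    tie: bool = False
    error: str | None = None


def train_two_layer(
    benchmarks: Mapping[str, BenchmarkDataset | Sequence[BenchmarkDataset]],
    cfg: DescriptorConfig = DescriptorConfig(),
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
    threshold: float = 0.5,
    cache: FeatureCache | None = None,
) -> TwoLayerModel:
    """Assemble the two-layer model from benchmark datasets.

    ``benchmarks`` maps ``general`` plus the three class labels to either a
    single split dataset or a list of replicate datasets; given replicates,
    the one whose grid-searched model has the highest CV accuracy is kept
    (ties to the lowest replicate index).
    """
    required = {"general", *CLASS_ORDER}
    if set(benchmarks) != required:
        raise ValueError(f"benchmarks must have keys {sorted(required)}")
    cache = cache or FeatureCache(cfg)
    chosen: dict[str, TrainedBinaryModel] = {}
    for label, entry in benchmarks.items():
        reps = [entry] if isinstance(entry, BenchmarkDataset) else list(entry)
        models = [
            train_binary(ds, cfg, C_grid, gamma_grid, seed=seed, cache=cache)
            for ds in reps
        ]
        best = max(range(len(models)), key=lambda i: (models[i].cv_accuracy, -i))
        chosen[label] = models[best]
    return TwoLayerModel(
        layer1=chosen["general"],
        layer2={c: chosen[c] for c in CLASS_ORDER},
        threshold=threshold,
        descriptor_config=cfg,
    )


def predict_two_layer(
    model: TwoLayerModel,
    seqs: Sequence[ProteinSequence],
    threshold: float | None = None,
) -> list[PredictionResult]:
    """Run the two-layer cascade over sequences.

    Layer-1 probability is computed for every valid sequence; those with
    probability strictly above the threshold continue to layer 2 and get the
    argmax class (ties broken by fixed alphabetical class order and
    flagged).  Sequences failing validation yield an error entry and the
    run continues.
    """
    thr = model.threshold if threshold is None else threshold
    kept, rejected = validate_and_filter(seqs)
    results: dict[str, PredictionResult] = {}
    for r in rejected:
        results[r.id] = PredictionResult(
            sequence_id=r.id, layer1_probability=float("nan"),
            is_fertility=False, class_scores=None, assigned_class=None,
            error=r.reason,
        )
    if kept:
        cache = FeatureCache(model.descriptor_config)
        X = cache.matrix(kept)
        p1 = model.layer1.predict_proba(X)
        fertile_idx = np.flatnonzero(p1 > thr)
        scores = {
            c: model.layer2[c].predict_proba(X[fertile_idx])
            for c in CLASS_ORDER
        } if len(fertile_idx) else {}
        fert_pos = {int(i): j for j, i in enumerate(fertile_idx)}
        for i, s in enumerate(kept):
            if i in fert_pos:
                j = fert_pos[i]
                cs = {c: float(scores[c][j]) for c in CLASS_ORDER}
                best = max(cs.values())
                winners = [c for c in CLASS_ORDER if cs[c] == best]
                results[s.id] = PredictionResult(
                    sequence_id=s.id, layer1_probability=float(p1[i]),
                    is_fertility=True, class_scores=cs,
                    assigned_class=winners[0], tie=len(winners) > 1,
                )
            else:
                results[s.id] = PredictionResult(
                    sequence_id=s.id, layer1_probability=float(p1[i]),
                    is_fertility=False, class_scores=None, assigned_class=None,
                )
    return [results[s.id] for s in seqs]
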