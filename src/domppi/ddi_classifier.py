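"""RBF-kernel SVM classifier for domain pairs.

Wraps scikit-learn's libsvm binding behind the pipeline's contracts:
leakage-free per-fold min-max normalization, repeated stratified 5-fold
cross-validation with a stability stopping rule, a deterministic (c, g)
grid search, and a text-format model file that reloads bit-exactly.

Labels are {1, 0} at every external interface (interacting /
noninteracting); the {+1, -1} encoding the underlying solver needs is an
internal detail.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .featurization import MinMaxNormalizer
from .metrics import (
    ConfusionCounts,
    MetricReport,
    compute_metrics,
    confusion_from_predictions,
    roc_auc,
)

# Default (c, g): the grid-search optimum used when search is skipped.
DEFAULT_C = 9.1896
DEFAULT_G = 3.0314

# Customary libsvm-style search lattices (powers of two, step 2).
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_G_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))

MODEL_FORMAT = "domppi-ddi-model/1"


@dataclass(frozen=True)
class SvmConfig:
    """Classifier and cross-validation settings."""

    c: float = DEFAULT_C
    g: float = DEFAULT_G
    seed: int = 0
    n_folds: int = 5
    n_repeats: int = 5
    max_repeats: int = 20
    stability_tol: float = 0.5  # percentage points of repeat-accuracy std
    y_min: float = -1.0
    y_max: float = 1.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0:
            raise ValueError("c and g must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1 or self.max_repeats < self.n_repeats:
            raise ValueError("need 1 <= n_repeats <= max_repeats")


@dataclass(frozen=True)
class RepeatResult:
    """One cross-validation repeat: pooled out-of-fold outcome."""

    counts: ConfusionCounts
    report: MetricReport
    auc: float


@dataclass(frozen=True)
class CvReport:
    """Per-repeat results with mean/max aggregates."""

    repeats: tuple[RepeatResult, ...]
    config: SvmConfig

    _METRICS = ("acc", "sn", "spe", "pre", "f1", "mcc")

    def _values(self, metric: str) -> list[float]:
        if metric == "auc":
            return [r.auc for r in self.repeats]
        return [r.report.as_dict()[metric] for r in self.repeats]

    @property
    def mean(self) -> dict[str, float]:
        return {m: statistics.fmean(self._values(m)) for m in (*self._METRICS, "auc")}

    @property
    def max(self) -> dict[str, float]:
        return {m: max(self._values(m)) for m in (*self._METRICS, "auc")}


def _check_matrix(X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-finite feature value at row {bad[0]}, column {bad[1]}")
    if y is not None:
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValueError("labels and feature matrix disagree on sample count")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0 or 1")
    return X


@dataclass
class DdiModel:
    """A trained domain-pair classifier plus its normalizer.

    Persistence stores the training set and configuration rather than the
    fitted solver state; training is deterministic, so reloading refits to
    a bit-identical model.
    """

    config: SvmConfig
    normalizer: MinMaxNormalizer
    X_train: np.ndarray
    y_train: np.ndarray
    _svc: SVC = field(repr=False)

    @classmethod
    def train(cls, X_raw, y, config: SvmConfig | None = None) -> "DdiModel":
        config = config or SvmConfig()
        X = _check_matrix(X_raw, y)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes")
        normalizer = MinMaxNormalizer.fit(X, config.y_min, config.y_max)
        svc = SVC(kernel="rbf", C=config.c, gamma=config.g)
        svc.fit(normalizer.transform(X), np.where(y == 1, 1, -1))
        return cls(
            config=config, normalizer=normalizer,
            X_train=X.copy(), y_train=y.copy(), _svc=svc,
        )

    def decision_values(self, X_raw) -> np.ndarray:
        X = _check_matrix(X_raw)
        if X.shape[0] == 0:
            return np.empty(0)
        return self._svc.decision_function(self.normalizer.transform(X))

    def predict(self, X_raw) -> np.ndarray:
        X = _check_matrix(X_raw)
        if X.shape[0] == 0:
            return np.empty(0, dtype=int)
        raw = self._svc.predict(self.normalizer.transform(X))
        return np.where(raw == 1, 1, 0)

    def save(self, path) -> None:
        payload = {
            "format": MODEL_FORMAT,
            "config": {
                "c": self.config.c, "g": self.config.g, "seed": self.config.seed,
                "n_folds": self.config.n_folds, "n_repeats": self.config.n_repeats,
                "max_repeats": self.config.max_repeats,
                "stability_tol": self.config.stability_tol,
                "y_min": self.config.y_min, "y_max": self.config.y_max,
            },
            "normalizer": self.normalizer.to_dict(),
            "n_features": int(self.X_train.shape[1]),
            "training_vectors": [[float(v) for v in row] for row in self.X_train],
            "training_labels": self.y_train.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "DdiModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError(f"unrecognized model format in {path}")
        config = SvmConfig(**payload["config"])
        X = np.asarray(payload["training_vectors"], dtype=float)
        y = np.asarray(payload["training_labels"], dtype=int)
        model = cls.train(X, y, config)
        # the stored normalizer must match the refit one; trust but verify
        stored = MinMaxNormalizer.from_dict(payload["normalizer"])
        if not (
            np.array_equal(stored.x_min, model.normalizer.x_min)
            and np.array_equal(stored.x_max, model.normalizer.x_max)
        ):
            raise ValueError(f"normalizer in {path} inconsistent with training data")
        return model


def predict_pairs(model: DdiModel, X_raw) -> np.ndarray:
    """Hard {1, 0} labels, order-preserving, one per input row."""
    return model.predict(X_raw)


def _out_of_fold(
    X: np.ndarray, y: np.ndarray, config: SvmConfig, random_state: int
) -> tuple[np.ndarray, np.ndarray]:
    """One repeat: pooled out-of-fold predictions and decision values.

    The normalizer is refit on each fold's training portion so no
    evaluation-fold statistic leaks into the transform.
    """
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=random_state
    )
    pred = np.empty(len(y), dtype=int)
    dec = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        model = DdiModel.train(X[train_idx], y[train_idx], config)
        pred[test_idx] = model.predict(X[test_idx])
        dec[test_idx] = model.decision_values(X[test_idx])
    return pred, dec


def cross_validate(X_raw, y, config: SvmConfig | None = None) -> CvReport:
    """Repeated stratified k-fold cross-validation.

    Runs ``n_repeats`` repeats minimum and continues (up to ``max_repeats``)
    until the standard deviation of the repeat accuracies drops below
    ``stability_tol`` percentage points. Repeats differ only in the fold
    shuffle; the whole report is reproducible from the seed.
    """
    config = config or SvmConfig()
    X = _check_matrix(X_raw, y)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires both classes")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"need at least {config.n_folds} samples per class for stratified "
            f"{config.n_folds}-fold cross-validation"
        )
    repeats: list[RepeatResult] = []
    accs: list[float] = []
    while True:
        r = len(repeats)
        pred, dec = _out_of_fold(X, y, config, config.seed + r)
        counts_r = confusion_from_predictions(y, pred)
        report = compute_metrics(counts_r)
        auc, _ = roc_auc(dec, y)
        repeats.append(RepeatResult(counts=counts_r, report=report, auc=auc))
        accs.append(report.acc)
        n = len(repeats)
        if n < config.n_repeats:
            continue
        if n >= config.max_repeats:
            break
        if n >= 2 and statistics.stdev(accs) < config.stability_tol:
            break
    return CvReport(repeats=tuple(repeats), config=config)


def grid_search(
    X_raw,
    y,
    c_grid=DEFAULT_C_GRID,
    g_grid=DEFAULT_G_GRID,
    config: SvmConfig | None = None,
) -> tuple[float, float]:
    """Pick (c, g) maximizing mean cross-validated accuracy.

    One fixed stratified fold split (from the seed) is shared by every grid
    point; ties break toward smaller c, then smaller g.
    """
    config = config or SvmConfig()
    if not len(c_grid) or not len(g_grid):
        raise ValueError("grids must be nonempty")
    X = _check_matrix(X_raw, y)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search requires both classes")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    splits = list(skf.split(X, y))
    best: tuple[float, float, float] | None = None  # (acc, c, g)
    for c in sorted(set(float(v) for v in c_grid)):
        for g in sorted(set(float(v) for v in g_grid)):
            cfg = replace(config, c=c, g=g)
            correct = 0
            for train_idx, test_idx in splits:
                model = DdiModel.train(X[train_idx], y[train_idx], cfg)
                correct += int(np.sum(model.predict(X[test_idx]) == y[test_idx]))
            acc = correct / len(y)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, c, g)
    return best[1], best[2]
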