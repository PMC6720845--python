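"""Feature assembly for domain pairs.

Subcellular-location encoding, correlation-based feature screening,
min–max normalization onto a fixed target interval, and construction of
the 20-dimensional domain-pair vectors fed to the classifier.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .physchem import PhyschemProfile

#: Subcellular location categories and their integer codes.
LOCATION_CODES: dict[str, int] = {
    "Nuclear": 1,
    "Plasma membrane": 2,
    "Extracellular": 3,
    "Cytoplasmic": 4,
    "Mitochondrial": 5,
    "Endoplasmic reticulum": 6,
    "Peroxisomal": 7,
    "Lysosomal": 8,
    "Golgi": 9,
    "Vacuolar": 10,
}
LOCATION_NAMES: dict[int, str] = {v: k for k, v in LOCATION_CODES.items()}
_LOCATION_LOOKUP = {k.lower(): v for k, v in LOCATION_CODES.items()}

#: The ten per-domain model features, in fixed order.
MODEL_FEATURES: tuple[str, ...] = (
    "n_residues",
    "theoretical_pi",
    "n_negative",
    "n_positive",
    "n_atoms",
    "ext_coefficient_1",
    "instability_index",
    "aliphatic_index",
    "gravy",
    "location_code",
)


def encode_location(location_name: str) -> int:
    """Map a location category name (case-insensitive) to its 1–10 code."""
    code = _LOCATION_LOOKUP.get(location_name.strip().lower())
    if code is None:
        valid = ", ".join(LOCATION_CODES)
        raise ValueError(
            f"unknown location {location_name!r}; valid categories are: {valid}"
        )
    return code


def domain_feature_vector(profile: PhyschemProfile, location_code: int) -> np.ndarray:
    """The raw (unnormalized) 10-feature vector for one domain."""
    if not 1 <= int(location_code) <= 10:
        raise ValueError(f"location code must be in 1..10, got {location_code}")
    values = [
        getattr(profile, name) for name in MODEL_FEATURES if name != "location_code"
    ]
    values.append(float(location_code))
    return np.asarray(values, dtype=float)


def correlation_filter(
    matrix: np.ndarray, threshold: float, *, names: Sequence[str] | None = None
) -> list[int]:
    """Greedy correlation screen over feature columns.

    Columns are visited in their declared order; a column is dropped when
    its absolute Pearson correlation with any already-retained column
    strictly exceeds ``threshold``. Constant columns correlate with nothing
    (treated as r = 0, with a warning) and are therefore retained.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("feature matrix must be 2-D with at least 2 rows")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    std = X.std(axis=0)
    constant = std == 0.0
    if constant.any():
        idx = np.flatnonzero(constant).tolist()
        labels = [names[i] for i in idx] if names else idx
        warnings.warn(
            f"constant feature column(s) {labels}: correlations treated as 0",
            stacklevel=2,
        )
    retained: list[int] = []
    for j in range(X.shape[1]):
        keep = True
        for k in retained:
            if constant[j] or constant[k]:
                continue
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if abs(r) > threshold:
                keep = False
                break
        if keep:
            retained.append(j)
    return retained


@dataclass
class MinMaxNormalizer:
    """Per-feature affine rescaling onto [y_min, y_max].

    y = (y_max - y_min) * (x - x_min) / (x_max - x_min) + y_min

    ``x_min``/``x_max`` are learned once from a training matrix and reused
    unchanged on evaluation data; evaluation values outside the training
    range are clipped to the target interval. A constant training feature
    maps to the midpoint of the target interval.
    """

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float = -1.0
    y_max: float = 1.0

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape or self.x_min.ndim != 1:
            raise ValueError("x_min/x_max must be 1-D arrays of equal length")
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max must be >= x_min for every feature")
        if not self.y_max > self.y_min:
            raise ValueError("y_max must exceed y_min")

    @classmethod
    def fit(
        cls, matrix: np.ndarray, y_min: float = -1.0, y_max: float = 1.0
    ) -> "MinMaxNormalizer":
        X = np.asarray(matrix, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("training matrix must be 2-D with at least 2 rows")
        x_min = X.min(axis=0)
        x_max = X.max(axis=0)
        if np.any(x_max == x_min):
            cols = np.flatnonzero(x_max == x_min).tolist()
            warnings.warn(
                f"feature column(s) {cols} are constant on the training set; "
                "they will map to the midpoint of the target range",
                stacklevel=2,
            )
        return cls(x_min=x_min, x_max=x_max, y_min=y_min, y_max=y_max)

    @property
    def n_features(self) -> int:
        return self.x_min.shape[0]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(matrix, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got {X.shape[1]}"
            )
        span = self.x_max - self.x_min
        mid = 0.5 * (self.y_min + self.y_max)
        with np.errstate(divide="ignore", invalid="ignore"):
            Y = (self.y_max - self.y_min) * (X - self.x_min) / span + self.y_min
        Y = np.where(span == 0.0, mid, Y)
        return np.clip(Y, self.y_min, self.y_max)

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(matrix, dtype=float))
        if Y.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got {Y.shape[1]}"
            )
        span = self.x_max - self.x_min
        X = (Y - self.y_min) * span / (self.y_max - self.y_min) + self.x_min
        return np.where(span == 0.0, self.x_min, X)

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MinMaxNormalizer":
        return cls(
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "MinMaxNormalizer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_pair_matrix(
    featurizer: Mapping[str, np.ndarray],
    pairs: Sequence[tuple],
    normalizer: MinMaxNormalizer | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Assemble 20-dimensional pair vectors for (id_a, id_b[, label]) rows.

    ``featurizer`` maps a domain id to its raw 10-feature vector. The first
    ten slots of each output row belong to the first-listed domain. Returns
    (matrix, labels) where labels is None when no row carries one.
    """
    rows = []
    labels: list[int] = []
    have_labels = None
    for pair in pairs:
        a, b = pair[0], pair[1]
        label = pair[2] if len(pair) > 2 else None
        for did in (a, b):
            if did not in featurizer:
                raise KeyError(f"no feature vector for domain {did!r}")
        rows.append(np.concatenate([featurizer[a], featurizer[b]]))
        if have_labels is None:
            have_labels = label is not None
        elif have_labels != (label is not None):
            raise ValueError("pair rows mix labeled and unlabeled entries")
        if label is not None:
            if label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {label!r}")
            labels.append(int(label))
    if rows:
        X = np.asarray(rows, dtype=float).reshape(len(rows), -1)
    else:
        X = np.empty((0, 2 * len(MODEL_FEATURES)))
    if normalizer is not None and len(rows):
        X = normalizer.transform(X)
    y = np.asarray(labels, dtype=int) if have_labels else None
    return X, y
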