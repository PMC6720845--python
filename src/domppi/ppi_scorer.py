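"""Protein-pair scoring: fusion of the domain-pair interaction score
channel with the classifier's predicted-pair ratio.

For a protein pair (m, n):

* every domain of m is crossed with every domain of n;
* each domain pair's positive score lambda (falling back to a background
  score when the table has no entry) is log-normalized against the table
  maximum, d = log(lambda) / log(s_max), and the per-pair values are
  aggregated (maximum by default) into ``d_mn``;
* the fraction of those domain pairs the classifier labels interacting is
  ``p_ij``;
* the fused probability is ``p_mn = A * d_mn + B * p_ij`` (A = B = 0.5 by
  default).

The (A, B) weights are picked on a 7x7 lattice over {0, 0.1, ..., 0.6} and
the decision threshold on a coarse 10-point grid (0.10-0.55 step 0.05)
followed by a +/-0.01 refinement, choosing where the false-negative and
false-positive rates are small and nearly equal.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import ConfusionCounts, confusion_from_predictions, fn_fp_rates, roc_auc

DEFAULT_INTERACTION_CUTOFF = 1.5
DEFAULT_LATTICE: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(7))
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(
    round(0.10 + 0.05 * i, 2) for i in range(10)
)
BACKGROUND_PERCENTILE = 0.2


@dataclass(frozen=True)
class ProteinRecord:
    """A protein id with its ordered domain architecture (length >= 1)."""

    protein_id: str
    domain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be nonempty")
        if not self.domain_ids:
            raise ValueError(f"protein {self.protein_id}: empty domain architecture")
        object.__setattr__(self, "domain_ids", tuple(self.domain_ids))


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def twentieth_percentile_background(
    lambdas: Sequence[float], cutoff: float = DEFAULT_INTERACTION_CUTOFF
) -> float:
    """Background-noise score: the 20%-position value of the interacting
    (score >= cutoff) lambdas sorted ascending (1-based index ceil(0.2*n))."""
    vals = sorted(v for v in lambdas if v >= cutoff)
    if not vals:
        raise ValueError(
            f"no scores >= {cutoff}; cannot derive a background score"
        )
    idx = max(1, math.ceil(BACKGROUND_PERCENTILE * len(vals)))
    return vals[idx - 1]


@dataclass
class InteractionScoreTable:
    """Orientation-insensitive lambda scores per domain pair.

    Unscored pairs resolve to ``background_score``. ``s_max`` is the
    largest stored lambda and must exceed 1 so the log normalization is
    well defined.
    """

    scores: dict[tuple[str, str], float]
    background_score: float
    interaction_cutoff: float = DEFAULT_INTERACTION_CUTOFF
    s_max: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("score table must contain at least one entry")
        normalized: dict[tuple[str, str], float] = {}
        for (a, b), lam in self.scores.items():
            if lam <= 0:
                raise ValueError(f"lambda for pair ({a}, {b}) must be positive")
            normalized[_pair_key(a, b)] = float(lam)
        self.scores = normalized
        self.s_max = max(self.scores.values())
        if self.s_max <= 1:
            raise ValueError(f"s_max must exceed 1, got {self.s_max}")
        if self.background_score <= 1:
            raise ValueError(
                f"background score must exceed 1, got {self.background_score}"
            )

    @classmethod
    def from_scores(
        cls,
        rows: Sequence[tuple[str, str, float]],
        background_score: float | None = None,
        interaction_cutoff: float = DEFAULT_INTERACTION_CUTOFF,
    ) -> "InteractionScoreTable":
        """Build from (id_a, id_b, lambda) rows.

        When no background score is supplied, the 20th-percentile rule is
        applied to the rows at or above the interaction cutoff.
        """
        scores: dict[tuple[str, str], float] = {}
        for a, b, lam in rows:
            key = _pair_key(a, b)
            if key in scores and scores[key] != float(lam):
                raise ValueError(f"conflicting scores for pair ({a}, {b})")
            scores[key] = float(lam)
        if background_score is None:
            background_score = twentieth_percentile_background(
                scores.values(), interaction_cutoff
            )
        return cls(
            scores=scores,
            background_score=background_score,
            interaction_cutoff=interaction_cutoff,
        )

    def get(self, a: str, b: str) -> float | None:
        return self.scores.get(_pair_key(a, b))

    def lookup(self, a: str, b: str) -> float:
        return self.scores.get(_pair_key(a, b), self.background_score)


def enumerate_domain_pairs(
    prot_a: ProteinRecord, prot_b: ProteinRecord
) -> list[tuple[str, str]]:
    """Full cross product of the two architectures (duplicates kept)."""
    return [(da, db) for da in prot_a.domain_ids for db in prot_b.domain_ids]


def normalize_score(lam: float, s_max: float) -> float:
    """d = log(lambda) / log(s_max), clamped into [0, 1]."""
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if s_max <= 1:
        raise ValueError(f"s_max must exceed 1, got {s_max}")
    return min(1.0, max(0.0, math.log(lam) / math.log(s_max)))


def protein_pair_dscore(
    prot_a: ProteinRecord,
    prot_b: ProteinRecord,
    table: InteractionScoreTable,
    agg: str = "max",
) -> float:
    """Aggregate normalized score over the pair's domain cross product."""
    values = [
        normalize_score(table.lookup(da, db), table.s_max)
        for da, db in enumerate_domain_pairs(prot_a, prot_b)
    ]
    if agg == "max":
        return max(values)
    if agg == "mean":
        return sum(values) / len(values)
    raise ValueError(f"unknown aggregation {agg!r} (use 'max' or 'mean')")


def predicted_ratio(
    prot_a: ProteinRecord,
    prot_b: ProteinRecord,
    model,
    featurizer: Mapping[str, np.ndarray],
) -> float:
    """Fraction of the domain cross product the classifier labels 1."""
    pairs = enumerate_domain_pairs(prot_a, prot_b)
    rows = []
    for da, db in pairs:
        for did in (da, db):
            if did not in featurizer:
                raise KeyError(f"no feature vector for domain {did!r}")
        rows.append(np.concatenate([featurizer[da], featurizer[db]]))
    labels = model.predict(np.asarray(rows, dtype=float))
    return float(np.sum(labels == 1)) / len(pairs)


def fuse(d_mn: float, p_ij: float, a_weight: float, b_weight: float) -> float:
    """Linear blend p_mn = A * d_mn + B * p_ij."""
    if a_weight < 0 or b_weight < 0:
        raise ValueError("weights must be nonnegative")
    return a_weight * d_mn + b_weight * p_ij


@dataclass(frozen=True)
class PpiScore:
    """Scored protein pair with full provenance."""

    protein_id_a: str
    protein_id_b: str
    d_mn: float
    p_ij: float
    p_mn: float
    predicted_label: int


@dataclass
class FusionConfig:
    """Fusion weights, search grids and the decision threshold."""

    a_weight: float = 0.5
    b_weight: float = 0.5
    lattice: tuple[float, ...] = DEFAULT_LATTICE
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    threshold: float = 0.26
    dscore_agg: str = "max"

    def __post_init__(self) -> None:
        if self.a_weight < 0 or self.b_weight < 0:
            raise ValueError("weights must be nonnegative")


def score_protein_pairs(
    pairs: Sequence[tuple],
    proteins: Mapping[str, ProteinRecord],
    model,
    featurizer: Mapping[str, np.ndarray],
    table: InteractionScoreTable,
    agg: str = "max",
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Per-pair (d_mn, p_ij) channel values for (id_a, id_b[, label]) rows.

    Classifier calls are batched over the whole pair list for speed.
    Returns (d, p, labels) with labels None when the rows carry none.
    """
    d_vals: list[float] = []
    offsets: list[tuple[int, int]] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    have_labels = len(pairs) > 0 and len(pairs[0]) > 2
    for pair in pairs:
        pa, pb = proteins[pair[0]], proteins[pair[1]]
        d_vals.append(protein_pair_dscore(pa, pb, table, agg))
        start = len(rows)
        for da, db in enumerate_domain_pairs(pa, pb):
            for did in (da, db):
                if did not in featurizer:
                    raise KeyError(f"no feature vector for domain {did!r}")
            rows.append(np.concatenate([featurizer[da], featurizer[db]]))
        offsets.append((start, len(rows)))
        if have_labels:
            labels.append(int(pair[2]))
    if rows:
        pred = np.asarray(model.predict(np.asarray(rows, dtype=float)))
    else:
        pred = np.empty(0, dtype=int)
    p_vals = [
        float(np.sum(pred[s:e] == 1)) / (e - s) if e > s else 0.0
        for s, e in offsets
    ]
    y = np.asarray(labels, dtype=int) if have_labels else None
    return np.asarray(d_vals), np.asarray(p_vals), y


def counts_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts when pairs scoring >= threshold are labeled 1."""
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return confusion_from_predictions(labels, pred)


def _threshold_key(counts: ConfusionCounts) -> tuple[float, float]:
    fnr, fpr = fn_fp_rates(counts)
    return (abs(fnr - fpr), fnr + fpr)


def select_threshold(
    scores,
    labels,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    refine_step: float = 0.01,
) -> tuple[float, pd.DataFrame]:
    """Pick the decision threshold where fn and fp rates are small and
    nearly equal.

    Coarse stage: over the grid, minimize |fn - fp|, breaking ties by
    fn + fp, then by the smaller threshold. Refinement stage: re-evaluate
    at the pick +/- ``refine_step`` and move only on a strict improvement
    in (|fn - fp|, fn + fp), so exact ties keep the coarse pick.

    Returns the chosen threshold and a per-threshold diagnostic table.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold selection requires both classes")
    records = []

    def evaluate(t: float, stage: str) -> tuple[tuple[float, float], ConfusionCounts]:
        c = counts_at_threshold(scores, y, t)
        fnr, fpr = fn_fp_rates(c)
        records.append(
            {
                "threshold": t, "stage": stage,
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                "fn_rate": fnr, "fp_rate": fpr,
                "acc": 100.0 * (c.tp + c.tn) / c.total,
                "sn": 100.0 * c.tp / (c.tp + c.fn),
            }
        )
        return (abs(fnr - fpr), fnr + fpr), c

    coarse_best: tuple[tuple[float, float, float], float] | None = None
    for t in threshold_grid:
        key, _ = evaluate(float(t), "coarse")
        full_key = (*key, float(t))
        if coarse_best is None or full_key < coarse_best[0]:
            coarse_best = (full_key, float(t))
    pick = coarse_best[1]
    best_key = coarse_best[0][:2]
    chosen = pick
    for t in (round(pick - refine_step, 10), round(pick + refine_step, 10)):
        key, _ = evaluate(t, "refine")
        if key < best_key:
            best_key = key
            chosen = t
    return chosen, pd.DataFrame.from_records(records)


def lattice_search(
    d_scores,
    p_ratios,
    labels,
    lattice: Sequence[float] = DEFAULT_LATTICE,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> tuple[float, float, pd.DataFrame]:
    """Search the (A, B) lattice for the best-fusing weight pair.

    Every lattice point is scored by its best accuracy over the threshold
    grid; the winner maximizes that accuracy, with AUC as tie-breaker, then
    smaller A, then smaller B. Returns (A*, B*, diagnostics) where the
    diagnostics table has one row per lattice point.
    """
    d = np.asarray(d_scores, dtype=float)
    p = np.asarray(p_ratios, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("lattice search requires both classes")
    records = []
    best = None  # ((-acc, -auc, a, b), a, b)
    for a in lattice:
        for b in lattice:
            s = a * d + b * p
            best_acc, best_t = -1.0, None
            for t in threshold_grid:
                c = counts_at_threshold(s, y, t)
                acc = 100.0 * (c.tp + c.tn) / c.total
                if acc > best_acc:
                    best_acc, best_t = acc, t
            if np.ptp(s) == 0:
                auc = 0.5  # constant scores carry no ranking information
            else:
                auc, _ = roc_auc(s, y)
            records.append(
                {"a": a, "b": b, "best_threshold": best_t, "acc": best_acc, "auc": auc}
            )
            key = (-best_acc, -auc, a, b)
            if best is None or key < best[0]:
                best = (key, a, b)
    return best[1], best[2], pd.DataFrame.from_records(records)


def predict_ppi(
    pairs: Sequence[tuple],
    proteins: Mapping[str, ProteinRecord],
    model,
    featurizer: Mapping[str, np.ndarray],
    table: InteractionScoreTable,
    config: FusionConfig | None = None,
) -> list[PpiScore]:
    """End-to-end scoring: label = 1 iff p_mn >= threshold."""
    config = config or FusionConfig()
    d, p, _ = score_protein_pairs(
        pairs, proteins, model, featurizer, table, config.dscore_agg
    )
    out = []
    for (pair, d_mn, p_ij) in zip(pairs, d, p):
        p_mn = fuse(float(d_mn), float(p_ij), config.a_weight, config.b_weight)
        out.append(
            PpiScore(
                protein_id_a=pair[0],
                protein_id_b=pair[1],
                d_mn=float(d_mn),
                p_ij=float(p_ij),
                p_mn=p_mn,
                predicted_label=int(p_mn >= config.threshold),
            )
        )
    return out
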