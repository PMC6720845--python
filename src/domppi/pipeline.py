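"""End-to-end orchestration: featurize, cross-validate, train, fuse,
search weights and threshold, and evaluate, all from one dataset."""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddi_classifier import CvReport, DdiModel, SvmConfig, cross_validate
from .featurization import build_pair_matrix, domain_feature_vector, encode_location
from .metrics import ConfusionCounts, MetricReport, compute_metrics, roc_auc
from .physchem import DomainSequence, PhyschemProfile, compute_profile
from .ppi_scorer import (
    FusionConfig,
    InteractionScoreTable,
    ProteinRecord,
    counts_at_threshold,
    lattice_search,
    score_protein_pairs,
    select_threshold,
)


def build_featurizer(
    profiles: Mapping[str, PhyschemProfile], location_codes: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Raw 10-feature vector per domain; every profile needs a location."""
    featurizer = {}
    for did, profile in profiles.items():
        if did not in location_codes:
            raise KeyError(f"no location annotation for domain {did!r}")
        featurizer[did] = domain_feature_vector(profile, location_codes[did])
    return featurizer


def profiles_from_sequences(
    sequences: Sequence[DomainSequence],
) -> dict[str, PhyschemProfile]:
    return {rec.domain_id: compute_profile(rec) for rec in sequences}


@dataclass
class PipelineResult:
    """Everything the full run produces, for reporting and assertions."""

    cv_report: CvReport
    model: DdiModel
    a_weight: float
    b_weight: float
    lattice_table: pd.DataFrame
    threshold: float
    threshold_table: pd.DataFrame
    ppi_counts: ConfusionCounts
    ppi_report: MetricReport
    ppi_auc: float
    d_scores: np.ndarray
    p_ratios: np.ndarray
    ppi_labels: np.ndarray


def run_pipeline(
    sequences: Sequence[DomainSequence],
    location_names: Mapping[str, str],
    ddi_pairs: Sequence[tuple[str, str, int]],
    ppi_pairs: Sequence[tuple[str, str, int]],
    architectures: Mapping[str, Sequence[str]],
    score_table: InteractionScoreTable,
    svm_config: SvmConfig | None = None,
    fusion_config: FusionConfig | None = None,
    search_weights: bool = True,
    search_threshold: bool = True,
) -> PipelineResult:
    """Run the whole method on in-memory inputs.

    Cross-validates the domain-pair classifier, trains the final model on
    all labeled domain pairs, scores every protein pair through both
    channels, optionally searches the (A, B) lattice and the decision
    threshold, and evaluates the fused scores.
    """
    svm_config = svm_config or SvmConfig()
    fusion = fusion_config or FusionConfig()

    profiles = profiles_from_sequences(sequences)
    codes = {did: encode_location(name) for did, name in location_names.items()}
    featurizer = build_featurizer(profiles, codes)

    X_ddi, y_ddi = build_pair_matrix(featurizer, ddi_pairs)
    cv_report = cross_validate(X_ddi, y_ddi, svm_config)
    model = DdiModel.train(X_ddi, y_ddi, svm_config)

    proteins = {
        pid: ProteinRecord(protein_id=pid, domain_ids=tuple(doms))
        for pid, doms in architectures.items()
    }
    d, p, y_ppi = score_protein_pairs(
        ppi_pairs, proteins, model, featurizer, score_table, fusion.dscore_agg
    )

    if search_weights:
        a_w, b_w, lattice_table = lattice_search(
            d, p, y_ppi, fusion.lattice, fusion.threshold_grid
        )
    else:
        a_w, b_w = fusion.a_weight, fusion.b_weight
        lattice_table = pd.DataFrame()
    fused = a_w * d + b_w * p

    if search_threshold:
        threshold, threshold_table = select_threshold(
            fused, y_ppi, fusion.threshold_grid
        )
    else:
        threshold, threshold_table = fusion.threshold, pd.DataFrame()

    counts = counts_at_threshold(fused, y_ppi, threshold)
    report = compute_metrics(counts)
    auc, _ = roc_auc(fused, y_ppi)
    return PipelineResult(
        cv_report=cv_report,
        model=model,
        a_weight=a_w,
        b_weight=b_w,
        lattice_table=lattice_table,
        threshold=threshold,
        threshold_table=threshold_table,
        ppi_counts=counts,
        ppi_report=report,
        ppi_auc=auc,
        d_scores=d,
        p_ratios=p,
        ppi_labels=y_ppi,
    )
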