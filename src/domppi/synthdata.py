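"""Self-contained synthetic datasets for the whole pipeline.

Generates, from one seed, every input the pipeline consumes: domain
sequences (FASTA), protein architectures, labeled domain-pair and
protein-pair tables, a positive domain-pair score table and per-domain
subcellular locations.

Class signal is planted in two independent channels so the score fusion is
genuinely exercised:

* sequence composition — interacting-class domains are drawn from a
  residue distribution tilted toward hydrophobic/aliphatic residues and
  noninteracting-class domains toward charged/polar ones, making the
  physicochemical features separable;
* lambda scores — domain pairs of interacting protein pairs receive
  log-normal scores with a higher location parameter (floored at the
  interaction cutoff 1.5) than the background entries attached to
  noninteracting pairs.

Setting ``composition_tilt``/``location_tilt`` to 0 and ``lambda_mu_pos``
equal to ``lambda_mu_neg`` removes all signal, which is used by the
null-control tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .featurization import LOCATION_NAMES
from .physchem import AA_ALPHABET, DomainSequence

# Residue-preference weights for the two domain classes (normalized later).
_POS_WEIGHTS = {
    "A": 3.0, "C": 1.0, "D": 0.3, "E": 0.3, "F": 2.5, "G": 1.0, "H": 0.5,
    "I": 3.0, "K": 0.3, "L": 3.0, "M": 2.0, "N": 0.5, "P": 0.8, "Q": 0.5,
    "R": 0.3, "S": 0.8, "T": 0.8, "V": 3.0, "W": 1.5, "Y": 1.5,
}
_NEG_WEIGHTS = {
    "A": 0.5, "C": 0.5, "D": 3.0, "E": 3.0, "F": 0.4, "G": 2.0, "H": 1.0,
    "I": 0.4, "K": 3.0, "L": 0.4, "M": 0.4, "N": 2.0, "P": 1.5, "Q": 2.0,
    "R": 2.5, "S": 2.5, "T": 2.0, "V": 0.5, "W": 0.3, "Y": 0.5,
}


def _class_profile(weights: dict[str, float], tilt: float) -> np.ndarray:
    w = np.array([weights[aa] for aa in AA_ALPHABET], dtype=float)
    w = w / w.sum()
    uniform = np.full(len(AA_ALPHABET), 1.0 / len(AA_ALPHABET))
    return (1.0 - tilt) * uniform + tilt * w


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-dataset generator."""

    n_positive_ppi: int = 427
    n_negative_ppi: int = 403
    n_positive_ddi: int = 1040
    n_negative_ddi: int = 1040
    n_domains_per_class: int = 120
    n_proteins_per_class: int = 150
    domain_count_range: tuple[int, int] = (1, 4)
    seq_len_range: tuple[int, int] = (50, 300)
    composition_tilt: float = 0.7
    location_tilt: float = 0.7
    lambda_mu_pos: float = 3.0
    lambda_mu_neg: float = -0.5
    lambda_sigma: float = 0.8
    interaction_cutoff: float = 1.5
    score_coverage_neg: float = 0.5
    # Sample both pair classes from one shared domain/protein pool instead
    # of the two class pools. Without this, pool identity alone is a signal
    # (domains recur across pairs), so the null configuration enables it.
    share_pools: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_positive_ppi", "n_negative_ppi", "n_positive_ddi",
            "n_negative_ddi", "n_domains_per_class", "n_proteins_per_class",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.composition_tilt <= 1.0:
            raise ValueError("composition_tilt must be in [0, 1]")
        if not 0.0 <= self.location_tilt <= 1.0:
            raise ValueError("location_tilt must be in [0, 1]")
        if self.lambda_mu_pos < self.lambda_mu_neg:
            raise ValueError("lambda_mu_pos must be >= lambda_mu_neg")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """A configuration with every class-separation knob disabled."""
        defaults = dict(
            composition_tilt=0.0,
            location_tilt=0.0,
            lambda_mu_pos=0.5,
            lambda_mu_neg=0.5,
            share_pools=True,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticDataset:
    """An in-memory dataset mirroring the on-disk file set."""

    config: GeneratorConfig
    sequences: list[DomainSequence]
    locations: dict[str, str]  # domain id -> location category name
    architectures: dict[str, tuple[str, ...]]  # protein id -> domain ids
    ddi_pairs: list[tuple[str, str, int]]
    ppi_pairs: list[tuple[str, str, int]]
    score_rows: list[tuple[str, str, float]]

    def truth_table(self) -> dict[str, dict[tuple[str, str], int]]:
        """Ground-truth labels exactly as drawn at generation time."""
        return {
            "ddi": {(a, b): lab for a, b, lab in self.ddi_pairs},
            "ppi": {(a, b): lab for a, b, lab in self.ppi_pairs},
        }

    def write(self, outdir) -> dict[str, Path]:
        """Write the six dataset files plus a manifest; returns the paths."""
        from . import io as dio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "domains.fasta",
            "architecture": outdir / "architecture.tsv",
            "locations": outdir / "locations.tsv",
            "ddi_pairs": outdir / "ddi_pairs.tsv",
            "ppi_pairs": outdir / "ppi_pairs.tsv",
            "scores": outdir / "scores.tsv",
            "manifest": outdir / "manifest.json",
        }
        dio.write_fasta(paths["fasta"], self.sequences)
        dio.write_architecture(paths["architecture"], self.architectures)
        dio.write_locations(paths["locations"], self.locations)
        dio.write_pair_table(paths["ddi_pairs"], self.ddi_pairs)
        dio.write_pair_table(paths["ppi_pairs"], self.ppi_pairs)
        dio.write_score_rows(paths["scores"], self.score_rows)
        manifest = {
            "config": dataclasses.asdict(self.config),
            "counts": {
                "domains": len(self.sequences),
                "proteins": len(self.architectures),
                "ddi_pairs": len(self.ddi_pairs),
                "ppi_pairs": len(self.ppi_pairs),
                "score_rows": len(self.score_rows),
            },
            "files": {k: v.name for k, v in paths.items() if k != "manifest"},
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _sample_distinct_pairs(
    rng: np.random.Generator, ids: list[str], count: int, what: str
) -> list[tuple[str, str]]:
    all_pairs = list(combinations(ids, 2))
    if count > len(all_pairs):
        raise ValueError(
            f"cannot draw {count} distinct {what} pairs from {len(ids)} ids "
            f"(only {len(all_pairs)} constructible)"
        )
    idx = rng.choice(len(all_pairs), size=count, replace=False)
    return [all_pairs[i] for i in idx]


def _location_probs(tilt: float, favored: range) -> np.ndarray:
    p = np.full(10, (1.0 - tilt) / 10.0)
    for code in favored:
        p[code - 1] += tilt / len(favored)
    return p


def _interacting_lambda(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    lam = math.exp(rng.normal(cfg.lambda_mu_pos, cfg.lambda_sigma))
    return max(lam, cfg.interaction_cutoff)


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a complete, mutually consistent dataset from the config seed.

    The same seed always yields a byte-identical file set.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    aa = np.array(list(AA_ALPHABET))
    profiles = {
        1: _class_profile(_POS_WEIGHTS, cfg.composition_tilt),
        0: _class_profile(_NEG_WEIGHTS, cfg.composition_tilt),
    }
    loc_probs = {
        1: _location_probs(cfg.location_tilt, range(1, 6)),
        0: _location_probs(cfg.location_tilt, range(6, 11)),
    }

    # domain pools: DP* interacting-class, DN* noninteracting-class
    width = len(str(cfg.n_domains_per_class))
    pools = {
        1: [f"DP{i + 1:0{width}d}" for i in range(cfg.n_domains_per_class)],
        0: [f"DN{i + 1:0{width}d}" for i in range(cfg.n_domains_per_class)],
    }
    sequences: list[DomainSequence] = []
    locations: dict[str, str] = {}
    lo, hi = cfg.seq_len_range
    for cls in (1, 0):
        for did in pools[cls]:
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(aa, size=length, p=profiles[cls]))
            sequences.append(DomainSequence(domain_id=did, sequence=seq))
            code = int(rng.choice(np.arange(1, 11), p=loc_probs[cls]))
            locations[did] = LOCATION_NAMES[code]

    ddi_pairs: list[tuple[str, str, int]] = []
    if cfg.share_pools:
        union = pools[1] + pools[0]
        drawn = _sample_distinct_pairs(
            rng, union, cfg.n_positive_ddi + cfg.n_negative_ddi, "DDI"
        )
        pos_ddi = drawn[: cfg.n_positive_ddi]
        neg_ddi = drawn[cfg.n_positive_ddi :]
    else:
        pos_ddi = _sample_distinct_pairs(
            rng, pools[1], cfg.n_positive_ddi, "positive DDI"
        )
        neg_ddi = _sample_distinct_pairs(
            rng, pools[0], cfg.n_negative_ddi, "negative DDI"
        )
    ddi_pairs.extend((a, b, 1) for a, b in pos_ddi)
    ddi_pairs.extend((a, b, 0) for a, b in neg_ddi)

    # proteins: PP* built from the interacting pool, PN* from the other
    pwidth = len(str(cfg.n_proteins_per_class))
    architectures: dict[str, tuple[str, ...]] = {}
    prot_ids = {1: [], 0: []}
    dlo, dhi = cfg.domain_count_range
    for cls, prefix in ((1, "PP"), (0, "PN")):
        for i in range(cfg.n_proteins_per_class):
            pid = f"{prefix}{i + 1:0{pwidth}d}"
            n_dom = int(rng.integers(dlo, dhi + 1))
            pool = pools[1] + pools[0] if cfg.share_pools else pools[cls]
            doms = tuple(rng.choice(pool, size=n_dom, replace=True))
            architectures[pid] = doms
            prot_ids[cls].append(pid)

    ppi_pairs: list[tuple[str, str, int]] = []
    if cfg.share_pools:
        union_prots = prot_ids[1] + prot_ids[0]
        drawn = _sample_distinct_pairs(
            rng, union_prots, cfg.n_positive_ppi + cfg.n_negative_ppi, "PPI"
        )
        pos_ppi = drawn[: cfg.n_positive_ppi]
        neg_ppi = drawn[cfg.n_positive_ppi :]
    else:
        pos_ppi = _sample_distinct_pairs(
            rng, prot_ids[1], cfg.n_positive_ppi, "positive PPI"
        )
        neg_ppi = _sample_distinct_pairs(
            rng, prot_ids[0], cfg.n_negative_ppi, "negative PPI"
        )
    ppi_pairs.extend((a, b, 1) for a, b in pos_ppi)
    ppi_pairs.extend((a, b, 0) for a, b in neg_ppi)

    # score table: interacting-distribution lambdas for every positive DDI
    # pair and for every domain pair of a positive protein pair; low-
    # distribution entries for a sampled fraction of negative-pair domain
    # pairs (the remainder exercises the background fallback).
    score_map: dict[tuple[str, str], float] = {}

    def key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    for a, b in pos_ddi:
        score_map[key(a, b)] = _interacting_lambda(rng, cfg)
    for pa, pb, _ in (p for p in ppi_pairs if p[2] == 1):
        for da in architectures[pa]:
            for db in architectures[pb]:
                k = key(da, db)
                if k not in score_map:
                    score_map[k] = _interacting_lambda(rng, cfg)
    for pa, pb, _ in (p for p in ppi_pairs if p[2] == 0):
        for da in architectures[pa]:
            for db in architectures[pb]:
                k = key(da, db)
                if k not in score_map and rng.random() < cfg.score_coverage_neg:
                    score_map[k] = math.exp(
                        rng.normal(cfg.lambda_mu_neg, cfg.lambda_sigma)
                    )
    score_rows = [(a, b, lam) for (a, b), lam in sorted(score_map.items())]

    return SyntheticDataset(
        config=cfg,
        sequences=sequences,
        locations=locations,
        architectures=architectures,
        ddi_pairs=ddi_pairs,
        ppi_pairs=ppi_pairs,
        score_rows=score_rows,
    )
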