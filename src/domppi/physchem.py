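"""Physicochemical property calculations on amino-acid sequences.

A self-contained equivalent of the classic web protein-parameter
calculators, operating on domain sequences: residue counts and mole-percent
composition, charged-residue totals, theoretical isoelectric point, molar
extinction coefficients, instability index, aliphatic index, grand average
of hydropathicity (GRAVY), whole-peptide atom count and average molecular
weight.

All numeric constants (hydropathy values, the 400-entry dipeptide
instability weight table, ionizable-group pKa values, residue masses and
atom counts) are shipped as human-readable TSV files under
:mod:`domppi.data`, each carrying a source-citation header, and are loaded
lazily on first use.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AA_ALPHABET)

#: Average mass of one water molecule (Da); restored once per chain.
WATER_MASS = 18.01524

#: Molar extinction coefficients at 280 nm (M^-1 cm^-1), Gill & von Hippel.
EXT_TRP = 5500
EXT_TYR = 1490
EXT_CYSTINE = 125

PI_TOLERANCE = 0.001
_PI_MAX_ITER = 100


class SequenceError(ValueError):
    """Raised when a sequence violates the 20-letter alphabet contract."""


def _data_rows(name: str) -> list[list[str]]:
    text = resources.files("domppi.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def hydropathy_table() -> dict[str, float]:
    """Kyte–Doolittle hydropathy values, one entry per residue."""
    return {r[0]: float(r[1]) for r in _data_rows("kyte_doolittle.tsv")}


@lru_cache(maxsize=None)
def diwv_table() -> dict[str, dict[str, float]]:
    """Guruprasad dipeptide instability weight values (20x20)."""
    rows = _data_rows("diwv.tsv")
    header = rows[0][1:]
    table = {}
    for row in rows[1:]:
        table[row[0]] = dict(zip(header, (float(v) for v in row[1:])))
    return table


@lru_cache(maxsize=None)
def pka_table() -> dict[str, tuple[float, str]]:
    """Bjellqvist pKa set: group -> (pKa, 'acidic'|'basic')."""
    return {r[0]: (float(r[1]), r[2]) for r in _data_rows("pka.tsv")}


@lru_cache(maxsize=None)
def residue_mass_table() -> dict[str, float]:
    """Average in-chain residue masses (Da)."""
    return {r[0]: float(r[1]) for r in _data_rows("residue_masses.tsv")}


@lru_cache(maxsize=None)
def residue_atom_table() -> dict[str, int]:
    """Atom counts of the free amino acids."""
    return {r[0]: int(r[2]) for r in _data_rows("residue_atoms.tsv")}


def validate_sequence(sequence: str, *, name: str = "sequence") -> str:
    """Check a sequence against the 20-letter alphabet.

    Returns the sequence unchanged; raises :class:`SequenceError` naming the
    first offending 1-based position otherwise.
    """
    if not sequence:
        raise SequenceError(f"{name}: sequence must be nonempty")
    for i, ch in enumerate(sequence):
        if ch not in _VALID_RESIDUES:
            raise SequenceError(
                f"{name}: invalid residue {ch!r} at position {i + 1}; "
                f"allowed characters are {AA_ALPHABET}"
            )
    return sequence


@dataclass(frozen=True)
class DomainSequence:
    """A domain identifier plus its amino-acid sequence (uppercase)."""

    domain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be nonempty")
        validate_sequence(self.sequence, name=self.domain_id)

    def __len__(self) -> int:
        return len(self.sequence)


def _residues(seq: DomainSequence | str) -> str:
    if isinstance(seq, DomainSequence):
        return seq.sequence
    return validate_sequence(seq)


@dataclass(frozen=True)
class PhyschemProfile:
    """The full property set computed from one domain sequence.

    ``molecular_weight``, ``ext_coefficient_2`` and ``aa_composition`` are
    computed for completeness but are not part of the model feature vector.
    """

    n_residues: int
    theoretical_pi: float
    n_negative: int
    n_positive: int
    n_atoms: int
    ext_coefficient_1: int
    instability_index: float
    aliphatic_index: float
    gravy: float
    molecular_weight: float
    ext_coefficient_2: int
    aa_composition: dict[str, float] = field(repr=False)


def count_residues(seq: DomainSequence | str) -> tuple[dict[str, int], int]:
    """Per-residue counts plus the total residue count."""
    s = _residues(seq)
    counts = Counter(s)
    return {aa: counts.get(aa, 0) for aa in AA_ALPHABET}, len(s)


def aa_composition(seq: DomainSequence | str) -> dict[str, float]:
    """Mole-percent composition; values sum to 100."""
    counts, n = count_residues(seq)
    return {aa: 100.0 * c / n for aa, c in counts.items()}


def charged_counts(seq: DomainSequence | str) -> tuple[int, int]:
    """(negatively charged Asp+Glu, positively charged Arg+Lys).

    Histidine is deliberately excluded from the positive count.
    """
    s = _residues(seq)
    return s.count("D") + s.count("E"), s.count("R") + s.count("K")


def net_charge(seq: DomainSequence | str, ph: float) -> float:
    """Modeled net charge at a given pH.

    Henderson–Hasselbalch terms over the N-terminus, C-terminus and the
    ionizable side chains (D, E, C, Y, H, K, R) with the Bjellqvist pKa
    set, including the residue-specific terminal pKa overrides.
    """
    s = _residues(seq)
    counts = Counter(s)
    table = pka_table()
    charge = 0.0
    groups: list[tuple[float, str, int]] = []
    nterm = table.get(f"Nterm:{s[0]}", table["Nterm"])
    cterm = table.get(f"Cterm:{s[-1]}", table["Cterm"])
    groups.append((*nterm, 1))
    groups.append((*cterm, 1))
    for group, (pka, kind) in table.items():
        if group.startswith(("Nterm", "Cterm")):
            continue
        groups.append((pka, kind, counts.get(group, 0)))
    for pka, kind, n in groups:
        if n == 0:
            continue
        if kind == "basic":
            charge += n / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def theoretical_pi(seq: DomainSequence | str) -> float:
    """pH at which the modeled net charge is zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so a unique root
    exists; bisection runs to a tolerance of 0.001 pH units.
    """
    s = _residues(seq)
    lo, hi = 0.0, 14.0
    for _ in range(_PI_MAX_ITER):
        mid = 0.5 * (lo + hi)
        if net_charge(s, mid) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < PI_TOLERANCE:
            break
    return 0.5 * (lo + hi)


def extinction_coefficients(seq: DomainSequence | str) -> tuple[int, int]:
    """Molar extinction coefficients at 280 nm: (cystine-assuming, reduced).

    The first value assumes every pair of cysteines forms a cystine bridge
    (125 M^-1 cm^-1 per bridge, unpaired Cys contributes nothing); the
    second assumes all cysteines reduced.
    """
    s = _residues(seq)
    base = EXT_TRP * s.count("W") + EXT_TYR * s.count("Y")
    return base + EXT_CYSTINE * (s.count("C") // 2), base


def instability_index(seq: DomainSequence | str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    s = _residues(seq)
    if len(s) < 2:
        raise ValueError("instability index requires a sequence of length >= 2")
    diwv = diwv_table()
    total = 0.0
    for a, b in zip(s, s[1:]):
        total += diwv[a][b]
    return 10.0 / len(s) * total


def aliphatic_index(seq: DomainSequence | str) -> float:
    """Ikai aliphatic index: X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu)."""
    comp = aa_composition(seq)
    return comp["A"] + 2.9 * comp["V"] + 3.9 * (comp["I"] + comp["L"])


def gravy(seq: DomainSequence | str) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle value."""
    s = _residues(seq)
    table = hydropathy_table()
    return sum(table[ch] for ch in s) / len(s)


def atom_count(seq: DomainSequence | str) -> int:
    """Total atoms of the whole peptide.

    Sum of in-chain residue atoms (free amino acid minus one water, i.e.
    minus 3 atoms) plus 3 for the single terminal water restored per chain.
    """
    s = _residues(seq)
    atoms = residue_atom_table()
    return sum(atoms[ch] - 3 for ch in s) + 3


def molecular_weight(seq: DomainSequence | str) -> float:
    """Average molecular weight (Da): residue masses plus one water."""
    s = _residues(seq)
    masses = residue_mass_table()
    return sum(masses[ch] for ch in s) + WATER_MASS


def compute_profile(seq: DomainSequence | str) -> PhyschemProfile:
    """Compute every profile field for one sequence (length >= 2)."""
    s = _residues(seq)
    _, n = count_residues(s)
    n_neg, n_pos = charged_counts(s)
    ext1, ext2 = extinction_coefficients(s)
    return PhyschemProfile(
        n_residues=n,
        theoretical_pi=theoretical_pi(s),
        n_negative=n_neg,
        n_positive=n_pos,
        n_atoms=atom_count(s),
        ext_coefficient_1=ext1,
        instability_index=instability_index(s),
        aliphatic_index=aliphatic_index(s),
        gravy=gravy(s),
        molecular_weight=molecular_weight(s),
        ext_coefficient_2=ext2,
        aa_composition=aa_composition(s),
    )
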