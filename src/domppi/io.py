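"""Readers and writers for every file format the pipeline touches.

Plain text throughout: FASTA for sequences and TSV for everything else
(architectures, pair tables, score tables, locations, profiles, reports).
Comment lines start with '#'; the tab is the only delimiter. Parse errors
carry 1-based line numbers.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

from .featurization import encode_location
from .physchem import DomainSequence, PhyschemProfile, AA_ALPHABET
from .ppi_scorer import DEFAULT_INTERACTION_CUTOFF, InteractionScoreTable, ProteinRecord

_FASTA_WRAP = 60

#: Profile TSV column order (fixed for diffability).
PROFILE_COLUMNS: tuple[str, ...] = (
    "domain_id",
    "n_residues",
    "molecular_weight",
    "n_atoms",
    "theoretical_pi",
    "n_negative",
    "n_positive",
    "ext_coefficient_1",
    "ext_coefficient_2",
    "instability_index",
    "aliphatic_index",
    "gravy",
    *(f"pct_{aa}" for aa in AA_ALPHABET),
)


class ParseError(ValueError):
    """A malformed input file; the message carries the line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def read_fasta(path) -> list[DomainSequence]:
    """Parse a FASTA file into domain sequences, order-preserving.

    Headers are parsed up to the first whitespace as the domain id;
    sequence letters are uppercased; wrapped and unwrapped bodies and
    CRLF line endings are all accepted. Duplicate ids and empty records
    are errors.
    """
    records: list[DomainSequence] = []
    seen: dict[str, int] = {}
    current_id: str | None = None
    current_lineno = 0
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(path, current_lineno, f"empty record {current_id!r}")
        records.append(DomainSequence(domain_id=current_id, sequence=seq))

    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(path, lineno, "empty FASTA header")
                domain_id = header.split()[0]
                if domain_id in seen:
                    raise ParseError(
                        path, lineno,
                        f"duplicate domain id {domain_id!r} "
                        f"(first seen at line {seen[domain_id]})",
                    )
                seen[domain_id] = lineno
                current_id, current_lineno, chunks = domain_id, lineno, []
            else:
                if current_id is None:
                    raise ParseError(path, lineno, "sequence data before any header")
                chunks.append(line.strip().upper())
        flush()
    return records


def write_fasta(path, sequences: Iterable[DomainSequence]) -> None:
    with open(path, "w") as fh:
        for rec in sequences:
            fh.write(f">{rec.domain_id}\n")
            for i in range(0, len(rec.sequence), _FASTA_WRAP):
                fh.write(rec.sequence[i : i + _FASTA_WRAP] + "\n")


def _data_lines(path):
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_pair_table(path) -> list[tuple]:
    """(id_a, id_b) or (id_a, id_b, label) rows; labels must be 0 or 1."""
    pairs: list[tuple] = []
    for lineno, fields in _data_lines(path):
        fields = [f.strip() for f in fields]
        if len(fields) == 2:
            pairs.append((fields[0], fields[1]))
        elif len(fields) == 3:
            if fields[2] not in ("0", "1"):
                raise ParseError(
                    path, lineno, f"label must be 0 or 1, got {fields[2]!r}"
                )
            pairs.append((fields[0], fields[1], int(fields[2])))
        else:
            raise ParseError(
                path, lineno, f"expected 2 or 3 tab-separated fields, got {len(fields)}"
            )
    return pairs


def write_pair_table(path, pairs: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for pair in pairs:
            fh.write("\t".join(str(v) for v in pair) + "\n")


def read_architecture(path) -> dict[str, ProteinRecord]:
    """protein_id followed by one tab-separated field per domain id."""
    proteins: dict[str, ProteinRecord] = {}
    for lineno, fields in _data_lines(path):
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) < 2:
            raise ParseError(
                path, lineno, "expected a protein id and at least one domain id"
            )
        pid = fields[0]
        if pid in proteins:
            raise ParseError(path, lineno, f"duplicate protein id {pid!r}")
        proteins[pid] = ProteinRecord(protein_id=pid, domain_ids=tuple(fields[1:]))
    return proteins


def write_architecture(path, architectures: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for pid, doms in architectures.items():
            fh.write("\t".join([pid, *doms]) + "\n")


def read_locations(path) -> dict[str, int]:
    """domain_id -> location code, validating names against the vocabulary."""
    codes: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        fields = [f.strip() for f in fields]
        if len(fields) != 2:
            raise ParseError(
                path, lineno, f"expected 2 tab-separated fields, got {len(fields)}"
            )
        did, name = fields
        if did in codes:
            raise ParseError(path, lineno, f"duplicate domain id {did!r}")
        try:
            codes[did] = encode_location(name)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
    return codes


def write_locations(path, locations: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for did, name in locations.items():
            fh.write(f"{did}\t{name}\n")


def read_score_table(
    path,
    background_score: float | None = None,
    interaction_cutoff: float = DEFAULT_INTERACTION_CUTOFF,
) -> InteractionScoreTable:
    """TSV (id_a, id_b, lambda) -> score table.

    The background score, unless supplied, is derived by the
    20th-percentile rule over entries at or above the cutoff.
    """
    rows: list[tuple[str, str, float]] = []
    for lineno, fields in _data_lines(path):
        fields = [f.strip() for f in fields]
        if len(fields) != 3:
            raise ParseError(
                path, lineno, f"expected 3 tab-separated fields, got {len(fields)}"
            )
        try:
            lam = float(fields[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad score {fields[2]!r}") from exc
        if lam <= 0:
            raise ParseError(path, lineno, f"score must be positive, got {lam}")
        rows.append((fields[0], fields[1], lam))
    if not rows:
        raise ParseError(path, 1, "score table is empty")
    return InteractionScoreTable.from_scores(rows, background_score, interaction_cutoff)


def write_score_rows(path, rows: Iterable[tuple[str, str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: domain_id_a, domain_id_b, lambda\n")
        for a, b, lam in rows:
            fh.write(f"{a}\t{b}\t{lam!r}\n")


def write_score_table(path, table: InteractionScoreTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# s_max = {table.s_max!r}\n")
        fh.write(f"# background_score = {table.background_score!r}\n")
        fh.write(f"# interaction_cutoff = {table.interaction_cutoff!r}\n")
        for (a, b), lam in sorted(table.scores.items()):
            fh.write(f"{a}\t{b}\t{lam!r}\n")


def write_profiles(path, profiles: Mapping[str, PhyschemProfile]) -> None:
    """One row per domain in the fixed profile column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for did, p in profiles.items():
            row = [
                did,
                str(p.n_residues),
                f"{p.molecular_weight:.6g}",
                str(p.n_atoms),
                f"{p.theoretical_pi:.6g}",
                str(p.n_negative),
                str(p.n_positive),
                str(p.ext_coefficient_1),
                str(p.ext_coefficient_2),
                f"{p.instability_index:.6g}",
                f"{p.aliphatic_index:.6g}",
                f"{p.gravy:.6g}",
                *(f"{p.aa_composition[aa]:.6g}" for aa in AA_ALPHABET),
            ]
            fh.write("\t".join(row) + "\n")


def read_profiles(path) -> dict[str, PhyschemProfile]:
    """Inverse of :func:`write_profiles` (values at serialized precision)."""
    profiles: dict[str, PhyschemProfile] = {}
    header: list[str] | None = None
    for lineno, fields in _data_lines(path):
        if header is None:
            header = fields
            if tuple(header) != PROFILE_COLUMNS:
                raise ParseError(path, lineno, "unexpected profile header")
            continue
        if len(fields) != len(PROFILE_COLUMNS):
            raise ParseError(
                path, lineno,
                f"expected {len(PROFILE_COLUMNS)} fields, got {len(fields)}",
            )
        vals = dict(zip(PROFILE_COLUMNS, fields))
        did = vals["domain_id"]
        if did in profiles:
            raise ParseError(path, lineno, f"duplicate domain id {did!r}")
        profiles[did] = PhyschemProfile(
            n_residues=int(vals["n_residues"]),
            theoretical_pi=float(vals["theoretical_pi"]),
            n_negative=int(vals["n_negative"]),
            n_positive=int(vals["n_positive"]),
            n_atoms=int(vals["n_atoms"]),
            ext_coefficient_1=int(vals["ext_coefficient_1"]),
            instability_index=float(vals["instability_index"]),
            aliphatic_index=float(vals["aliphatic_index"]),
            gravy=float(vals["gravy"]),
            molecular_weight=float(vals["molecular_weight"]),
            ext_coefficient_2=int(vals["ext_coefficient_2"]),
            aa_composition={aa: float(vals[f"pct_{aa}"]) for aa in AA_ALPHABET},
        )
    if header is None:
        raise ParseError(path, 1, "profile table is empty")
    return profiles
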