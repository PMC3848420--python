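"""Shared domain types, residue chemistry and file IO.

All residue coordinates in this package are 1-based and inclusive, matching
the residue numbering conventions of protein databases (e.g. an LRR domain
spanning Ile688-Thr1866 addresses sequence characters 688..1866).  Helpers
for 0-based half-open conversion are internal only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue synonym classes used by the repeat consensus patterns.
#: Aliphatic L/I/V, hydroxyl S/T, acid/amide E/D/Q/N and basic R/K are the
#: substitution groups conserved across RI-like repeats; ``o`` is a nonpolar
#: residue and ``x``/``X`` match anything.
DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "L": frozenset("LIV"),
    "S": frozenset("ST"),
    "E": frozenset("EDQN"),
    "R": frozenset("RK"),
    "o": frozenset("AVLIPFMWGC"),
    "x": frozenset(AMINO_ACIDS),
    "X": frozenset(AMINO_ACIDS),
}

DOMAIN_NAMES = ("uCARD", "NACHT", "AxP", "WH", "SH", "linker", "LRR")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class EmptyInputError(ValidationError):
    """Raised when a required input file contains no records."""


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open slice bounds."""
    return start - 1, end


def to_one_based(lo: int, hi: int) -> tuple[int, int]:
    """0-based half-open slice bounds -> 1-based inclusive span."""
    return lo + 1, hi


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with 1-based residue numbering."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, record_id=self.id)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(
                f"position {position} outside 1..{len(self.sequence)} "
                f"for record {self.id!r}"
            )
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence over a 1-based inclusive span."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValidationError(
                f"span {start}-{end} outside record {self.id!r} "
                f"(length {len(self.sequence)})"
            )
        lo, hi = to_zero_based(start, end)
        return self.sequence[lo:hi]


def validate_sequence(
    sequence: str, *, record_id: str = "?", allow_unknown: bool = False
) -> None:
    """Check a protein sequence against the 20-letter alphabet.

    ``allow_unknown`` additionally permits ``X``.  The analysis is
    pattern-based, so unknown residues are rejected by default: an ``X``
    cannot be assigned to a residue synonym class.
    """
    if not sequence:
        raise ValidationError(f"record {record_id!r}: empty sequence")
    allowed = set(AMINO_ACIDS) | ({"X"} if allow_unknown else set())
    for i, ch in enumerate(sequence, start=1):
        if ch not in allowed:
            raise ValidationError(
                f"record {record_id!r}: illegal residue {ch!r} at position {i}"
            )


@dataclasses.dataclass(frozen=True)
class DomainSpan:
    """A named region of the protein, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in DOMAIN_NAMES:
            raise ValidationError(f"unknown domain name {self.name!r}")
        if self.start > self.end or self.start < 1:
            raise ValidationError(
                f"domain {self.name}: invalid span {self.start}-{self.end}"
            )


def validate_architecture(spans: Iterable[DomainSpan]) -> list[DomainSpan]:
    """Check that domain spans are sorted and non-overlapping."""
    spans = sorted(spans, key=lambda s: s.start)
    for a, b in zip(spans, spans[1:]):
        if b.start <= a.end:
            raise ValidationError(f"domains {a.name} and {b.name} overlap")
    return spans


@dataclasses.dataclass
class ExonRecord:
    """One exon's protein-residue span.

    ``phase`` is the consensus column (1..repeat length) at which the exon's
    first encoded residue falls, filled in by the exon phasing stage; ``None``
    until computed or when the exon lies outside the repeat frame.
    """

    exon_number: int
    protein_start: int
    protein_end: int
    phase: int | None = None
    typical: bool | None = None
    score: float | None = None
    atypical_reason: str | None = None

    def __post_init__(self) -> None:
        if self.protein_start < 1 or self.protein_start > self.protein_end:
            raise ValidationError(
                f"exon {self.exon_number}: invalid span "
                f"{self.protein_start}-{self.protein_end}"
            )

    @property
    def length_aa(self) -> int:
        return self.protein_end - self.protein_start + 1


# ---------------------------------------------------------------------------
# FASTA IO (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, allow_unknown: bool = False) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased; record order is preserved.  Raises
    :class:`EmptyInputError` for an empty file and :class:`ValidationError`
    naming the record and position for an illegal residue character.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        validate_sequence(seq, record_id=rec.id, allow_unknown=allow_unknown)
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as standard wrapped FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# Exon table IO
# ---------------------------------------------------------------------------

EXON_COLUMNS = ("exon_number", "protein_start", "protein_end")


def read_exon_table(
    path: str | Path, *, require_non_overlapping: bool = True
) -> list[ExonRecord]:
    """Read a TSV of per-exon protein spans.

    Expects a header row with columns ``exon_number``, ``protein_start``,
    ``protein_end`` (1-based inclusive).  Records are returned sorted by
    exon number; overlapping spans raise a validation error.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty exon table {path}") from exc
    missing = [c for c in EXON_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"exon table {path}: missing columns {missing}")
    for col in EXON_COLUMNS:
        if not pd.api.types.is_integer_dtype(df[col]):
            try:
                df[col] = df[col].astype(int)
            except (ValueError, TypeError) as exc:
                raise ValidationError(
                    f"exon table {path}: non-integer values in column {col!r}"
                ) from exc
    df = df.sort_values("exon_number").reset_index(drop=True)
    exons = [
        ExonRecord(int(r.exon_number), int(r.protein_start), int(r.protein_end))
        for r in df.itertuples()
    ]
    if require_non_overlapping:
        by_start = sorted(exons, key=lambda e: e.protein_start)
        for a, b in zip(by_start, by_start[1:]):
            if b.protein_start <= a.protein_end:
                raise ValidationError(
                    f"exons {a.exon_number} and {b.exon_number} overlap "
                    f"({a.protein_start}-{a.protein_end} vs "
                    f"{b.protein_start}-{b.protein_end})"
                )
    return exons


def write_exon_table(exons: Iterable[ExonRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.exon_number, e.protein_start, e.protein_end) for e in exons],
        columns=list(EXON_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def gff3_to_exon_table(
    gff_path: str | Path, out_path: str | Path, *, cds_offset: int = 0
) -> list[ExonRecord]:
    """Convenience converter: derive protein spans from exon lines of a GFF3.

    Assumes exon features carry ``protein_start``/``protein_end`` attributes
    (pre-mapped to protein coordinates); full CDS-phase arithmetic from
    genomic coordinates is out of scope and remains the caller's
    responsibility.  The TSV written to ``out_path`` is the package contract.
    """
    exons = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            try:
                exons.append(
                    ExonRecord(
                        int(attrs["exon_number"]),
                        int(attrs["protein_start"]) + cds_offset,
                        int(attrs["protein_end"]) + cds_offset,
                    )
                )
            except KeyError as exc:
                raise ValidationError(
                    f"GFF3 exon line missing attribute {exc}"
                ) from exc
    exons.sort(key=lambda e: e.exon_number)
    write_exon_table(exons, out_path)
    return exons


# ---------------------------------------------------------------------------
# Molecular weight
# ---------------------------------------------------------------------------

def molecular_weight(
    record: ProteinRecord | str, *, monoisotopic: bool = False
) -> float:
    """Molecular weight of a protein in kDa.

    Sum of residue masses minus (n-1) waters, from the standard average
    (default) or monoisotopic mass table.  Rounding is left to presentation.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if "X" in seq:
        raise ValidationError(
            "cannot compute molecular weight: sequence contains unknown "
            "residue X and no average mass is configured for it"
        )
    daltons = _bio_molecular_weight(
        Seq(seq), seq_type="protein", monoisotopic=monoisotopic
    )
    return daltons / 1000.0
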