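"""Protein/peptide sequence I/O and validation.

Proteins travel as :class:`ProteinRecord` (FASTA in, FASTA out); peptide
tables (e.g. a physico-chemical reference table with external bioactivity
scores) travel as lists of :class:`PeptideEntry` read from CSV/TSV.

Only the 20 standard amino acids are accepted.  Ambiguity codes
(B, J, O, U, X, Z) are rejected rather than silently remapped, because the
downstream mass and pKa tables are defined only for the standard residues.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO

from .errors import (
    SchemaError,
    SequenceFormatError,
    SequenceValidationError,
    TableParseError,
)

#: The 20-letter standard amino-acid alphabet.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_FRACTION_TOKENS = {"myofibrillar", "sarcoplasmic"}


class Fraction(str, enum.Enum):
    """Muscle-protein fraction a precursor belongs to (metadata only)."""

    MYOFIBRILLAR = "myofibrillar"
    SARCOPLASMIC = "sarcoplasmic"
    UNSPECIFIED = "unspecified"


def validate_sequence(sequence: str, record: str = "<sequence>") -> str:
    """Validate ``sequence`` against the 20-letter alphabet.

    Returns the sequence unchanged.  Raises
    :class:`~pepdigest.errors.SequenceValidationError` naming the record and
    the 1-based position of the first illegal character.
    """
    if not sequence:
        raise SequenceValidationError(f"empty sequence in record {record!r}", record=record)
    for i, ch in enumerate(sequence, start=1):
        if ch not in AMINO_ACIDS:
            raise SequenceValidationError(
                f"illegal residue {ch!r} at position {i} in record {record!r}",
                record=record,
                position=i,
            )
    return sequence


@dataclass(frozen=True)
class ProteinRecord:
    """A precursor protein sequence.

    ``len(record)`` is the protein length N used by the profiling
    statistics (frequency of bioactive fragments per residue).
    """

    accession: str
    sequence: str
    name: str = ""
    fraction: Fraction = Fraction.UNSPECIFIED

    def __post_init__(self) -> None:
        if not self.accession:
            raise SequenceValidationError("accession must be non-empty")
        validate_sequence(self.sequence, record=self.accession)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideEntry:
    """A peptide with free-form scalar annotations (scores, printed values)."""

    sequence: str
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceValidationError("peptide sequence must be non-empty")


def _as_handle(source: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def _fraction_from_description(description: str) -> Fraction:
    for token in description.replace("|", " ").split():
        if token.lower() in _FRACTION_TOKENS:
            return Fraction(token.lower())
    return Fraction.UNSPECIFIED


def parse_fasta(source: Union[str, Path, TextIO]) -> list[ProteinRecord]:
    """Parse FASTA into validated :class:`ProteinRecord` objects, in order.

    Sequences are uppercased and whitespace-stripped.  An optional header
    token ``myofibrillar``/``sarcoplasmic`` sets the fraction tag.  Duplicate
    accessions and illegal residues raise validation errors; an input with
    no records at all raises :class:`~pepdigest.errors.SequenceFormatError`.
    """
    handle = _as_handle(source)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        accession = rec.id
        if accession in seen:
            raise SequenceValidationError(f"duplicate accession {accession!r}")
        seen.add(accession)
        name = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=validate_sequence(seq, record=accession),
                name=name,
                fraction=_fraction_from_description(rec.description or ""),
            )
        )
    if not records:
        raise SequenceFormatError("no FASTA records found in input")
    return records


def write_fasta(records: Iterable[ProteinRecord], target: Union[str, Path, TextIO]) -> None:
    """Write records as FASTA (accession, optional name and fraction tag)."""
    own = isinstance(target, (str, Path))
    handle = open(target, "w", encoding="utf-8") if own else target
    try:
        for rec in records:
            header = rec.accession
            if rec.name:
                header += f" {rec.name}"
            if rec.fraction is not Fraction.UNSPECIFIED:
                header += f" {rec.fraction.value}"
            handle.write(f">{header}\n{rec.sequence}\n")
    finally:
        if own:
            handle.close()


def _read_delimited(source: Union[str, Path, TextIO]) -> pd.DataFrame:
    """Read CSV or TSV; the delimiter is taken from the file extension
    (``.tsv``/``.tab`` means tab), defaulting to comma for streams."""
    sep = ","
    if isinstance(source, (str, Path)) and str(source).lower().endswith((".tsv", ".tab")):
        sep = "\t"
    try:
        return pd.read_csv(source, sep=sep, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise SequenceFormatError("empty table input") from exc


def load_peptide_table(
    source: Union[str, Path, TextIO],
    sequence_column: str = "sequence",
    numeric_columns: Sequence[str] = (),
) -> list[PeptideEntry]:
    """Load a peptide table into :class:`PeptideEntry` objects, row order kept.

    Columns other than ``sequence_column`` become annotations; those named
    in ``numeric_columns`` are parsed as floats (a bad cell raises
    :class:`~pepdigest.errors.TableParseError` with the row index).
    """
    df = _read_delimited(source)
    if sequence_column not in df.columns:
        raise SchemaError(
            f"required column {sequence_column!r} not found; got {list(df.columns)}"
        )
    entries: list[PeptideEntry] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        values = dict(zip(df.columns, row))
        seq = str(values.pop(sequence_column)).strip().upper()
        validate_sequence(seq, record=f"row {row_idx}")
        annotations: dict[str, object] = {}
        for col, raw in values.items():
            if raw is None or (isinstance(raw, float) and pd.isna(raw)):
                continue
            text = str(raw).strip()
            if not text:
                continue
            if col in numeric_columns:
                try:
                    annotations[col] = float(text.replace("−", "-"))
                except ValueError as exc:
                    raise TableParseError(
                        f"non-numeric value {text!r} in column {col!r} at row {row_idx}",
                        row=row_idx,
                    ) from exc
            else:
                annotations[col] = text
        entries.append(PeptideEntry(sequence=seq, annotations=annotations))
    return entries


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a DataFrame as CSV (or TSV for a ``.tsv`` extension), UTF-8."""
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")
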