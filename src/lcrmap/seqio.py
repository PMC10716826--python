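"""FASTA input/output, per-record statistics, and coordinate extraction.

Parsing and writing are delegated to Biopython's ``Bio.SeqIO``; this module
adds gzip sniffing (by magic bytes, not extension), a strict leading-content
check, and the lightweight record/statistics containers used across the
package. Coordinates are 1-based and inclusive on both ends throughout.
"""
from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]


@dataclass
class SequenceRecord:
    """One FASTA entry. Lowercase symbols encode soft-masked positions."""

    id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def upper(self) -> "SequenceRecord":
        """Un-mask: uppercase the sequence, preserving id and description."""
        return SequenceRecord(self.id, self.sequence.upper(), self.description)


@dataclass
class InfoRow:
    """Length and GC statistics for one record."""

    id: str
    length: int
    gc_percent: float
    empty: bool = False


def _open_text(path: PathLike) -> TextIO:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Read all records from a (possibly gzipped) FASTA file.

    Sequence lines are concatenated per header; character case is preserved.
    An empty file yields an empty list with a warning; non-whitespace content
    before the first ``>`` is a format error.
    """
    with _open_text(path) as handle:
        text_start = handle.read(1)
        while text_start and text_start.isspace():
            text_start = handle.read(1)
        if not text_start:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
        if text_start != ">":
            raise ValueError(f"{path}: content before first '>' header")
        handle.seek(0)
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, line_width: int = 80) -> None:
    """Write records as FASTA wrapped at ``line_width`` columns."""
    if line_width < 1:
        raise ValueError(f"line_width must be >= 1, got {line_width}")
    bio_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(bio_records)


def sequence_info(
    records: Iterable[SequenceRecord], acgt_only: bool = False
) -> List[InfoRow]:
    """Length and GC% per record, in input order.

    GC% counts G/C case-insensitively. The denominator is the full record
    length (ambiguity symbols included) by default; with ``acgt_only`` it is
    restricted to unambiguous A/C/G/T symbols. Records with a zero
    denominator report 0 with the ``empty`` flag set.
    """
    rows = []
    for rec in records:
        n = rec.length
        gc = sum(1 for s in rec.sequence if s in "GgCc")
        denom = (
            sum(1 for s in rec.sequence if s in "AaCcGgTt") if acgt_only else n
        )
        if denom == 0:
            rows.append(InfoRow(rec.id, n, 0.0, empty=True))
            continue
        rows.append(InfoRow(rec.id, n, 100.0 * gc / denom))
    return rows


def extract_subsequence(record: SequenceRecord, start: int, end: int) -> SequenceRecord:
    """Positions ``start..end`` (1-based, inclusive) of a record.

    The returned id is annotated with the coordinates.
    """
    if start < 1:
        raise ValueError(f"start must be >= 1, got {start}")
    if end > record.length:
        raise ValueError(f"end {end} exceeds record length {record.length}")
    if start > end:
        raise ValueError(f"inverted coordinates: start {start} > end {end}")
    return SequenceRecord(
        f"{record.id}:{start}-{end}",
        record.sequence[start - 1:end],
        record.description,
    )
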