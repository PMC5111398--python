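"""Strict readers and writers for the plain-text formats the pipeline touches.

FASTA and FASTQ parsing is deliberately strict: every rejection names the
offending record or line, duplicate identifiers are errors, and sequences are
canonicalised to upper-case ``A/C/G/T/N``.  Tables are tab-delimited UTF-8
with ``.`` as the decimal separator; the first row holds sample labels and the
first column species labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SequenceRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_depth_tsv",
    "read_depth_tsv",
    "write_assignments_tsv",
]

_VALID_SEQ = re.compile(r"^[ACGTN]*$")
FASTA_WRAP = 70


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A sequence with optional per-base phred+33 quality."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id: {self.id!r}")
        if not _VALID_SEQ.match(self.sequence):
            raise FormatError(f"record {self.id!r}: sequence contains invalid characters")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


def _check_bases(raw: str, line_no: int, path: Path) -> str:
    seq = raw.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise FormatError(f"{path}:{line_no}: invalid sequence characters {bad}")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) FASTA file into records, order preserved."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        rid = header.split()[0] if header.split() else ""
        if not rid:
            raise FormatError(f"{path}:{line_no}: empty FASTA header")
        if rid in seen:
            raise FormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(rid, "".join(chunks)))
        header, chunks = None, []

    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{i}: empty FASTA header")
            else:
                if header is None:
                    raise FormatError(f"{path}:{i}: sequence data before first header")
                chunks.append(_check_bases(line, i, path))
        flush(-1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), FASTA_WRAP):
                fh.write(rec.sequence[i : i + FASTA_WRAP] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line-record FASTQ (Sanger phred+33)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4:
        raise FormatError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq_raw, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"{path}:{i + 1}: expected '@' header")
        rid = head[1:].split()[0] if head[1:].split() else ""
        if not rid:
            raise FormatError(f"{path}:{i + 1}: empty FASTQ header")
        if rid in seen:
            raise FormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{i + 3}: expected '+' separator")
        seq = _check_bases(seq_raw, i + 2, path)
        if len(qual) != len(seq):
            raise FormatError(
                f"{path}: record {rid!r}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        records.append(SequenceRecord(rid, seq, qual))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labelled numeric matrix (rows = species, columns = samples).

    Returns a DataFrame with string row/column labels and float values.
    Ragged rows, duplicate labels, missing or non-numeric cells are errors.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.rstrip("\n")]
    if not rows:
        raise FormatError(f"{path}: empty table")
    header = rows[0]
    ncol = len(header)
    columns = header[1:]
    if len(set(columns)) != len(columns):
        raise FormatError(f"{path}: duplicate column labels")
    index: list[str] = []
    values: list[list[float]] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise FormatError(f"{path}: row {r} has {len(row)} fields, expected {ncol}")
        index.append(row[0])
        parsed = []
        for c, cell in enumerate(row[1:], start=2):
            if cell == "":
                raise FormatError(f"{path}: row {r} column {c}: missing value")
            try:
                parsed.append(float(cell))
            except ValueError:
                raise FormatError(f"{path}: row {r} column {c}: non-numeric cell {cell!r}") from None
        values.append(parsed)
    if len(set(index)) != len(index):
        raise FormatError(f"{path}: duplicate row labels")
    df = pd.DataFrame(values, index=index, columns=columns, dtype=float)
    if not ((df.to_numpy() >= 0) | df.isna().to_numpy()).all() or df.isna().to_numpy().any():
        bad = df.stack(future_stack=True)
        bad = bad[~(bad >= 0)]
        raise FormatError(f"{path}: negative or non-finite cells at {list(bad.index)[:5]}")
    return df


def write_matrix_tsv(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["species"] + [str(c) for c in table.columns]) + "\n")
        for label, row in table.iterrows():
            fh.write("\t".join([str(label)] + [format(v, "g") for v in row]) + "\n")


def write_depth_tsv(depth: Sequence[int], path: str | Path) -> None:
    """Per-reference depth as two columns: 0-based position, depth."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position\tdepth\n")
        for pos, d in enumerate(depth):
            fh.write(f"{pos}\t{int(d)}\n")


def read_depth_tsv(path: str | Path) -> list[int]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n")]
    out: list[int] = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{i}: expected 2 fields")
        out.append(int(fields[1]))
    return out


def write_assignments_tsv(assignments, path: str | Path) -> None:
    """Minimal per-read assignment export (read id, status, reference, 0-based
    position, strand, mismatch count)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tstatus\treference_id\tposition\tstrand\tmismatches\n")
        for a in assignments:
            ref = a.reference_id if a.reference_id is not None else "."
            pos = a.position if a.position is not None else "."
            strand = a.strand if a.strand is not None else "."
            mm = a.mismatches if a.mismatches is not None else "."
            fh.write(f"{a.read_id}\t{a.status}\t{ref}\t{pos}\t{strand}\t{mm}\n")
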