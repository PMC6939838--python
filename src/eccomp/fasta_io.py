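"""Byte-exact FASTA reading and writing.

Lossless storage is the whole point of this package, so the parser keeps
enough structure (per-record line lengths, blank lines, missing final
newline, any whitespace preamble) to re-serialize every record to the exact
bytes it was read from.  Only LF line endings are supported.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "parse_fasta_bytes",
    "records_to_bytes",
    "record_digest",
]

DEFAULT_WRAP = 60


def _wrap_lengths(n_residues: int, width: int) -> tuple[int, ...]:
    if n_residues == 0:
        return ()
    full, rest = divmod(n_residues, width)
    lengths = [width] * full
    if rest:
        lengths.append(rest)
    return tuple(lengths)


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record plus the layout metadata needed to rewrite it verbatim.

    ``description`` is the full header line after ``>`` (no newline);
    ``id`` is its first whitespace-delimited token.  ``line_lengths`` holds
    the length of every sequence line as found in the file (blank lines are
    legal and recorded as 0).  ``preamble`` carries any whitespace found
    before the header (normally empty), ``final_newline`` whether the
    record's last line is newline-terminated.
    """

    description: str
    residues: str
    line_lengths: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    final_newline: bool = True
    preamble: str = ""

    def __post_init__(self) -> None:
        if "\n" in self.residues or ">" in self.residues:
            raise ValueError("residues must not contain newlines or '>'")
        if self.line_lengths is None:
            object.__setattr__(
                self, "line_lengths", _wrap_lengths(len(self.residues), DEFAULT_WRAP)
            )
        if sum(self.line_lengths) != len(self.residues):
            raise ValueError(
                f"line_lengths sum {sum(self.line_lengths)} != residue count "
                f"{len(self.residues)} for record {self.id!r}"
            )

    @property
    def id(self) -> str:
        parts = self.description.split()
        return parts[0] if parts else ""

    @classmethod
    def new(
        cls, name: str, residues: str, width: int = DEFAULT_WRAP
    ) -> "SequenceRecord":
        """Build a record with uniform wrapping at ``width`` columns."""
        return cls(
            description=name,
            residues=residues,
            line_lengths=_wrap_lengths(len(residues), width),
        )

    def to_bytes(self, is_last: bool = True) -> bytes:
        head = f"{self.preamble}>{self.description}".encode("latin-1")
        lines = []
        pos = 0
        for ln in self.line_lengths:
            lines.append(self.residues[pos : pos + ln].encode("latin-1"))
            pos += ln
        body = b"\n".join([head] + lines)
        if self.final_newline or not is_last:
            body += b"\n"
        return body


def parse_fasta_bytes(data: bytes) -> list[SequenceRecord]:
    """Parse FASTA from raw bytes; record order defines sequence indices."""
    if not data.strip():
        raise ValueError("no sequences: input FASTA is empty")
    text = data.decode("latin-1")
    final_newline = text.endswith("\n")
    lines = text.split("\n")
    if final_newline:
        lines = lines[:-1]

    records: list[SequenceRecord] = []
    preamble_lines: list[str] = []
    header: str | None = None
    seq_lines: list[str] = []
    preamble = ""

    def flush(last: bool) -> None:
        nonlocal header, seq_lines, preamble
        if header is None:
            return
        records.append(
            SequenceRecord(
                description=header,
                residues="".join(seq_lines),
                line_lengths=tuple(len(s) for s in seq_lines),
                final_newline=final_newline if last else True,
                preamble=preamble,
            )
        )
        header, seq_lines, preamble = None, [], ""

    for lineno, line in enumerate(lines, start=1):
        if line.startswith(">"):
            flush(last=False)
            preamble = "".join(p + "\n" for p in preamble_lines)
            preamble_lines = []
            header = line[1:]
        elif header is not None:
            seq_lines.append(line)  # blank lines inside a record kept (length 0)
        else:
            if line.strip():
                raise ValueError(
                    f"malformed FASTA: line {lineno} precedes the first header"
                )
            preamble_lines.append(line)
    if header is None:
        raise ValueError("no sequences: input FASTA contains no '>' header")
    flush(last=True)
    return records


def records_to_bytes(records: Sequence[SequenceRecord]) -> bytes:
    return b"".join(
        rec.to_bytes(is_last=(i == len(records) - 1)) for i, rec in enumerate(records)
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    Raises ``ValueError`` for an empty file or for non-whitespace content
    before the first ``>`` header (with its line number).
    """
    return parse_fasta_bytes(Path(path).read_bytes())


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records; ``write_fasta(read_fasta(f), f2)`` makes f2 == f byte-wise."""
    Path(path).write_bytes(records_to_bytes(list(records)))


def record_digest(record: SequenceRecord) -> str:
    """128-bit digest of the record's serialized bytes (used for archive checks)."""
    return hashlib.blake2b(record.to_bytes(is_last=True), digest_size=16).hexdigest()
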