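"""Core sequence types, FASTA input, and match-report output.

A :class:`Sequence` is an identified string of symbols; an
:class:`Alphabet` is the ordered symbol set the engines index over
(DNA ``{A, C, G, T}`` by default).  Symbols outside the alphabet are
retained but treated as *universal mismatches*: they never compare equal
to any pattern symbol, not even to an identical character.  This gives
robust behaviour for ``N`` and other ambiguity codes without inventing
match semantics for them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alphabet",
    "DNA",
    "Sequence",
    "MatchReport",
    "read_fasta",
    "write_matches",
    "read_matches",
]

#: Code used for text symbols outside the alphabet.  Distinct from
#: :data:`UNKNOWN_PATTERN` so that an out-of-alphabet text symbol never
#: equals an out-of-alphabet pattern symbol (universal mismatch).
UNKNOWN_TEXT = -1
UNKNOWN_PATTERN = -2


class Alphabet:
    """An ordered set of distinct single-character symbols.

    The ordinal of a symbol is its position in ``symbols``; the
    occurrence index stores one row per ordinal.
    """

    def __init__(self, symbols: Iterable[str]):
        syms = tuple(symbols)
        if len(syms) != len(set(syms)):
            raise ValueError("alphabet symbols must be unique")
        if any(len(s) != 1 for s in syms):
            raise ValueError("alphabet symbols must be single characters")
        self.symbols: tuple[str, ...] = syms
        self._lookup = {s: l for l, s in enumerate(syms)}

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._lookup

    def __repr__(self) -> str:
        return f"Alphabet({''.join(self.symbols)!r})"

    def index(self, symbol: str) -> int:
        """Ordinal of ``symbol``; raises ``KeyError`` if absent."""
        return self._lookup[symbol]

    def encode(self, symbols: str, *, unknown: int = UNKNOWN_TEXT) -> np.ndarray:
        """Encode a symbol string as an ``int8`` code array.

        Alphabet members map to their ordinals; anything else maps to
        ``unknown``.
        """
        table = np.full(256, unknown, dtype=np.int8)
        for l, s in enumerate(self.symbols):
            table[ord(s)] = l
        raw = np.frombuffer(symbols.encode("ascii"), dtype=np.uint8)
        return table[raw]


#: The default nucleotide alphabet.
DNA = Alphabet("ACGT")


@dataclass(frozen=True)
class Sequence:
    """An identified symbol string (0-based indexing)."""

    id: str
    symbols: str

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def length(self) -> int:
        return len(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]

    def validate(self, alphabet: Alphabet = DNA) -> "Sequence":
        """Check every symbol is printable ASCII; returns self.

        Out-of-alphabet symbols are permitted (they fall into the
        designated unknown class) but must be encodable.
        """
        try:
            self.symbols.encode("ascii")
        except UnicodeEncodeError as e:
            raise ValueError(f"sequence {self.id!r} contains non-ASCII symbols") from e
        return self


@dataclass
class MatchReport:
    """End positions of factors within ``k`` edits of the pattern.

    ``entries`` holds ``(end_position, distance)`` pairs where
    ``end_position`` is the 0-based inclusive text offset of the
    factor's last symbol and ``distance`` the semi-global edit distance
    of the best factor ending there.
    """

    record_id: str
    entries: list[tuple[int, int]]
    k: int
    engine: str = "oracle"
    counters: object = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        prev = -1
        for end, dist in self.entries:
            if dist > self.k or dist < 0:
                raise ValueError(f"entry distance {dist} exceeds threshold k={self.k}")
            if end <= prev:
                raise ValueError("end positions must be strictly increasing")
            prev = end

    @property
    def end_positions(self) -> list[int]:
        return [e for e, _ in self.entries]


def read_fasta(path, *, case_fold: bool = True) -> list[Sequence]:
    """Read a (multi-record) FASTA file into a list of :class:`Sequence`.

    The header token up to the first whitespace becomes the id.  With
    ``case_fold`` (default) symbols are uppercased.  An empty file or a
    sequence line appearing before any header is an error.
    """
    path = Path(path)
    # Pre-scan for structural errors Biopython forgives silently.
    first_content_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first_content_line = (lineno, line)
                break
    if first_content_line is None:
        raise ValueError(f"{path}: empty FASTA file")
    lineno, line = first_content_line
    if not line.startswith(">"):
        raise ValueError(
            f"{path}: line {lineno}: sequence data before any '>' header"
        )
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            symbols = str(rec.seq)
            if case_fold:
                symbols = symbols.upper()
            records.append(Sequence(id=rec.id, symbols=symbols).validate())
    return records


def write_matches(report: MatchReport, fmt: str, path) -> None:
    """Write a match report as TSV or BED.

    TSV: a header line then one row per entry
    (``record_id``, 0-based ``end_position``, ``distance``).
    BED: 0-based half-open single-base intervals
    ``[end_position, end_position + 1)`` with name ``ed=<distance>``.
    Byte output is deterministic for a fixed report.
    """
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["record_id", "end_position", "distance"])
            for end, dist in report.entries:
                w.writerow([report.record_id, end, dist])
    elif fmt == "bed":
        with open(path, "w", newline="") as fh:
            for end, dist in report.entries:
                fh.write(f"{report.record_id}\t{end}\t{end + 1}\ted={dist}\n")
    else:
        raise ValueError(f"unknown match output format: {fmt!r}")


def read_matches(path, *, k: int | None = None, engine: str = "file") -> MatchReport:
    """Read a TSV match report written by :func:`write_matches`.

    ``k`` defaults to the largest distance present (0 for an empty
    report) since the TSV format does not store the threshold.
    """
    entries: list[tuple[int, int]] = []
    record_id = ""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["record_id", "end_position", "distance"]:
            raise ValueError(f"{path}: not a match-report TSV")
        for row in reader:
            record_id = row[0]
            entries.append((int(row[1]), int(row[2])))
    if k is None:
        k = max((d for _, d in entries), default=0)
    return MatchReport(record_id=record_id, entries=entries, k=k, engine=engine)
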