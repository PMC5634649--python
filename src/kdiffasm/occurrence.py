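"""Last-occurrence index: the dependency-elimination table.

For each indexed symbol the table stores, at every text prefix length
j (0..n), the largest 1-based position p <= j at which the symbol
occurs in the text, or 0 when it has not occurred yet:

    X[l, 0] = 0;  X[l, j] = j if T[j-1] = Q[l], else X[l, j-1].

Rows are mutually independent — each is computable from the text alone —
which is what lets every row of the distance grid be computed from the
previous row only: the in-row (horizontal) dependency collapses into a
"match at the last occurrence, then one insertion per later column"
chain read off this table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import occ_rows_kernel
from .sequences import DNA, Alphabet, Sequence, UNKNOWN_TEXT

__all__ = ["OccurrenceIndex", "build_occurrence_index", "last_occurrence"]


@dataclass
class OccurrenceIndex:
    """Per-symbol rows of last-occurrence positions over one text.

    ``table`` has one row per entry of ``row_of``; symbols of the
    alphabet that were not indexed (restricted build) are absent from
    ``row_of``.
    """

    alphabet: Alphabet
    table: np.ndarray  # (n_indexed_symbols, n+1) int32
    row_of: dict[str, int]
    n: int

    def row(self, symbol: str) -> np.ndarray:
        if symbol not in self.alphabet:
            raise KeyError(f"symbol {symbol!r} not in alphabet {self.alphabet!r}")
        if symbol not in self.row_of:
            raise KeyError(
                f"symbol {symbol!r} was not indexed (restricted build); "
                "rebuild with restrict_to=None"
            )
        return self.table[self.row_of[symbol]]


def build_occurrence_index(
    text,
    alphabet: Alphabet = DNA,
    *,
    restrict_to: str | None = None,
) -> OccurrenceIndex:
    """Build the last-occurrence table for ``text``.

    By default every alphabet symbol gets a row.  ``restrict_to``
    limits the build to the distinct symbols of the given string
    (typically the pattern) — observationally equivalent for the
    engines, which only ever read rows of pattern symbols, at
    O(|unique(pattern)| * n) memory instead of O(|alphabet| * n).
    Text symbols outside the alphabet never set any row.
    """
    if len(alphabet) == 0:
        raise ValueError("alphabet must be non-empty")
    symbols = text.symbols if isinstance(text, Sequence) else str(text)
    if restrict_to is None:
        indexed = list(alphabet.symbols)
    else:
        indexed = [s for s in dict.fromkeys(restrict_to) if s in alphabet]
    t = alphabet.encode(symbols, unknown=UNKNOWN_TEXT)
    codes = np.array([alphabet.index(s) for s in indexed], dtype=np.int8)
    if codes.shape[0] == 0:
        table = np.zeros((0, len(symbols) + 1), dtype=np.int32)
    else:
        table = occ_rows_kernel(t, codes)
    return OccurrenceIndex(
        alphabet=alphabet,
        table=table,
        row_of={s: r for r, s in enumerate(indexed)},
        n=len(symbols),
    )


def last_occurrence(index: OccurrenceIndex, symbol: str, j: int) -> int:
    """Largest 1-based position p <= j with text[p-1] = symbol (0 if none)."""
    if not 0 <= j <= index.n:
        raise ValueError(f"column {j} outside [0, {index.n}]")
    return int(index.row(symbol)[j])
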