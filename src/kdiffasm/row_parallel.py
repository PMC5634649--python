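"""Dependency-eliminated row-wise engine.

With the last-occurrence table in hand, every column of row i of the
distance grid is a function of row i-1 alone:

    D[i, j] = i                                        if j = 0
            = D[i-1, j-1]                              if T[j-1] = P[i-1]
            = 1 + min(D[i-1, j], D[i-1, j-1], i+j-1)   if X[l, j] = 0
            = 1 + min(D[i-1, j], D[i-1, j-1],
                      D[i-1, X[l,j]-1] + (j-1-X[l,j])) otherwise

where l indexes P[i-1] in the alphabet.  The horizontal dependency of
the classic recurrence is collapsed into the last term: match the
pattern symbol at its last occurrence before column j, then pay one
insertion per subsequent column.  Columns of a row are therefore
mutually independent; only the row-to-row order is serial.
"""

from __future__ import annotations

import numpy as np

from ._kernels import occ_rows_kernel, row_parallel_kernel
from .sequences import DNA, Alphabet, Sequence, UNKNOWN_PATTERN, UNKNOWN_TEXT

__all__ = ["compute_row", "run_row_parallel", "pattern_occ_rows"]


def pattern_occ_rows(text, pattern, alphabet: Alphabet = DNA):
    """Occurrence rows and per-pattern-position row indices.

    Returns ``(t, p, occ, sym_row)`` code arrays for the kernels: one
    occurrence row per distinct pattern code.  A pattern symbol outside
    the alphabet never occurs in the encoded text (universal mismatch),
    so its row is naturally all zeros.
    """
    tsym = text.symbols if isinstance(text, Sequence) else str(text)
    psym = pattern.symbols if isinstance(pattern, Sequence) else str(pattern)
    t = alphabet.encode(tsym, unknown=UNKNOWN_TEXT)
    p = alphabet.encode(psym, unknown=UNKNOWN_PATTERN)
    codes, sym_row = np.unique(p, return_inverse=True)
    if codes.shape[0] == 0:
        occ = np.zeros((1, t.shape[0] + 1), dtype=np.int32)
        sym_row = np.zeros(0, dtype=np.int64)
    else:
        occ = occ_rows_kernel(t, codes.astype(np.int8))
    return t, p, occ, sym_row.astype(np.int64)


def compute_row(
    previous: np.ndarray,
    i: int,
    pattern_symbol_matches: np.ndarray,
    occ_row: np.ndarray,
) -> np.ndarray:
    """One grid row from the previous row, evaluated column-wise.

    ``pattern_symbol_matches[j]`` says whether text[j-1] equals the
    current pattern symbol (j >= 1); ``occ_row`` is that symbol's
    last-occurrence row.  Every output column reads only ``previous`` —
    never another output column — so any evaluation order (or a fully
    parallel one) gives the same row.  This reference form evaluates
    each column independently with scalar reads; the production path is
    the compiled kernel in :func:`run_row_parallel`.
    """
    previous = np.asarray(previous)
    n = previous.shape[0] - 1
    if i < 1:
        raise ValueError("row index i must be >= 1")
    out = np.empty(n + 1, dtype=np.int32)
    out[0] = i
    for j in range(1, n + 1):
        if pattern_symbol_matches[j]:
            out[j] = previous[j - 1]
        else:
            x = int(occ_row[j])
            chain = i + j - 1 if x == 0 else int(previous[x - 1]) + (j - 1 - x)
            out[j] = 1 + min(int(previous[j]), int(previous[j - 1]), chain)
    return out


def run_row_parallel(
    text,
    pattern,
    *,
    keep_matrix: bool = False,
    alphabet: Alphabet = DNA,
) -> np.ndarray:
    """Run the row-wise engine; equals the oracle grid cell for cell.

    Returns the full (m+1, n+1) grid when ``keep_matrix``, else the
    final row (O(n) working memory, a two-row rolling buffer).
    """
    t, p, occ, sym_row = pattern_occ_rows(text, pattern, alphabet)
    out = row_parallel_kernel(t, p, occ, sym_row, keep_matrix)
    return out if keep_matrix else out[0]
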