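"""Reference dynamic-programming engine and match extraction.

The semi-global edit-distance grid ``D`` has shape (m+1, n+1) for a
pattern of length m against a text of length n.  Row 0 is zero (a match
may begin at any text position), column 0 of row i is i, and

    D[i, j] = D[i-1, j-1]                                 if T[j-1] = P[i-1]
            = 1 + min(D[i-1, j], D[i, j-1], D[i-1, j-1])  otherwise.

``D[m, j]`` is then the smallest edit distance between the pattern and
any factor of the text ending at (1-based) column j.  This module is
the ground-truth oracle the parallel engines are checked against.
"""

from __future__ import annotations

import numpy as np

from ._kernels import dp_matrix_kernel, dp_final_row_kernel, global_distance_kernel
from .sequences import DNA, Alphabet, Sequence, UNKNOWN_PATTERN, UNKNOWN_TEXT

__all__ = [
    "edit_distance_matrix",
    "edit_distance_final_row",
    "global_edit_distance",
    "extract_matches",
    "result_array",
    "matrix_to_tsv",
]


def _codes(seq, alphabet: Alphabet, *, pattern: bool = False) -> np.ndarray:
    symbols = seq.symbols if isinstance(seq, Sequence) else str(seq)
    unknown = UNKNOWN_PATTERN if pattern else UNKNOWN_TEXT
    return alphabet.encode(symbols, unknown=unknown)


def edit_distance_matrix(text, pattern, alphabet: Alphabet = DNA) -> np.ndarray:
    """Full (m+1, n+1) semi-global distance grid as an int32 array."""
    t = _codes(text, alphabet)
    p = _codes(pattern, alphabet, pattern=True)
    return dp_matrix_kernel(t, p)

def edit_distance_final_row(text, pattern, alphabet: Alphabet = DNA) -> np.ndarray:
    """Row m of the grid only, computed with O(n) working memory."""
    t = _codes(text, alphabet)
    p = _codes(pattern, alphabet, pattern=True)
    return dp_final_row_kernel(t, p)


def global_edit_distance(a, b, alphabet: Alphabet = DNA) -> int:
    """Levenshtein distance between two whole strings (symmetric).

    Differs from the semi-global grid only in the top-row
    initialisation (D[0, j] = j: the entire first string must be
    consumed).
    """
    # Symbol identity, not alphabet membership, decides a match here:
    # global distance is a property of the two strings alone.
    sa = a.symbols if isinstance(a, Sequence) else str(a)
    sb = b.symbols if isinstance(b, Sequence) else str(b)
    joint = Alphabet(dict.fromkeys(sa + sb)) if (sa + sb) else alphabet
    ca = joint.encode(sa)
    cb = joint.encode(sb)
    return int(global_distance_kernel(ca, cb))


def extract_matches(final_row: np.ndarray, k: int) -> list[tuple[int, int]]:
    """End positions within threshold, from the grid's final row.

    Returns ``(j, distance)`` for every 0-based text offset j with
    ``final_row[j+1] <= k``, in increasing j.
    """
    if k < 0:
        raise ValueError("threshold k must be non-negative")
    row = np.asarray(final_row)
    hits = np.flatnonzero(row[1:] <= k)
    return [(int(j), int(row[j + 1])) for j in hits]


def result_array(final_row: np.ndarray, k: int) -> np.ndarray:
    """The -1-sentinel encoding of the hit set.

    ``result[j] = j`` when the best factor ending at text offset j is
    within k edits of the pattern, -1 otherwise.
    """
    if k < 0:
        raise ValueError("threshold k must be non-negative")
    row = np.asarray(final_row)
    n = row.shape[0] - 1
    out = np.full(n, -1, dtype=np.int64)
    hits = np.flatnonzero(row[1:] <= k)
    out[hits] = hits
    return out


def matrix_to_tsv(matrix: np.ndarray, path) -> None:
    """Debug dump of a distance grid, row-major with an ``m n`` header."""
    m = matrix.shape[0] - 1
    n = matrix.shape[1] - 1
    with open(path, "w") as fh:
        fh.write(f"# m={m}\tn={n}\n")
        for row in matrix:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")
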