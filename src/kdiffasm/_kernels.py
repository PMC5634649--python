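"""Numba-compiled inner loops shared by the three engines.

All kernels operate on ``int8`` code arrays produced by
``Alphabet.encode``: alphabet symbols are 0..sigma-1, out-of-alphabet
text symbols are -1 and out-of-alphabet pattern symbols -2, so an
unknown symbol never compares equal to anything (universal mismatch).

The occurrence table passed to the row-parallel and warp kernels has one
row per *pattern position's* symbol row index (``sym_row``), built over
1-based text positions: ``occ[r, j]`` is the largest position ``p <= j``
with ``text[p-1]`` equal to that symbol, 0 if none.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Counter slot layout for the warp kernel (kept in one int64 vector so
# the jitted code stays allocation-free).
CTR_D_READS = 0
CTR_X_READS = 1
CTR_SHARED_READS = 2
CTR_WRITES = 3
CTR_SHUFFLES = 4
CTR_SYNCS = 5
N_COUNTERS = 6


@njit(cache=False)
def dp_matrix_kernel(t, p):
    """Classic semi-global recurrence; returns the full (m+1, n+1) grid.

    D[0, j] = 0 (a match may start anywhere), D[i, 0] = i, and each
    interior cell depends on its left, upper and upper-left neighbours.
    """
    n = t.shape[0]
    m = p.shape[0]
    D = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        D[i, 0] = i
        for j in range(1, n + 1):
            if t[j - 1] == p[i - 1]:
                D[i, j] = D[i - 1, j - 1]
            else:
                a = D[i - 1, j]
                b = D[i, j - 1]
                c = D[i - 1, j - 1]
                best = a
                if b < best:
                    best = b
                if c < best:
                    best = c
                D[i, j] = 1 + best
    return D


@njit(cache=False)
def dp_final_row_kernel(t, p):
    """Final row of the semi-global grid with O(n) working state."""
    n = t.shape[0]
    m = p.shape[0]
    prev = np.zeros(n + 1, dtype=np.int32)
    cur = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur[0] = i
        for j in range(1, n + 1):
            if t[j - 1] == p[i - 1]:
                cur[j] = prev[j - 1]
            else:
                best = prev[j]
                if cur[j - 1] < best:
                    best = cur[j - 1]
                if prev[j - 1] < best:
                    best = prev[j - 1]
                cur[j] = 1 + best
        prev, cur = cur, prev
    return prev.copy()


@njit(cache=False)
def global_distance_kernel(a, b):
    """Plain Levenshtein distance (global alignment of whole strings)."""
    n = a.shape[0]
    m = b.shape[0]
    prev = np.arange(n + 1).astype(np.int32)
    cur = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur[0] = i
        for j in range(1, n + 1):
            if a[j - 1] == b[i - 1]:
                cur[j] = prev[j - 1]
            else:
                best = prev[j]
                if cur[j - 1] < best:
                    best = cur[j - 1]
                if prev[j - 1] < best:
                    best = prev[j - 1]
                cur[j] = 1 + best
        prev, cur = cur, prev
    return prev[n]


@njit(cache=False)
def occ_rows_kernel(t, codes):
    """Last-occurrence rows for the given symbol codes, one per code.

    Row r is computable from the text alone (no cross-row dependency):
    occ[r, j] = j when text[j-1] bears codes[r], else occ[r, j-1].
    """
    n = t.shape[0]
    nrows = codes.shape[0]
    occ = np.zeros((nrows, n + 1), dtype=np.int32)
    for r in range(nrows):
        c = codes[r]
        last = 0
        for j in range(1, n + 1):
            if t[j - 1] == c:
                last = j
            occ[r, j] = last
    return occ


@njit(cache=False)
def row_parallel_kernel(t, p, occ, sym_row, keep_matrix):
    """Dependency-eliminated engine: each row from the previous row only.

    For j >= 1 the cell is previous[j-1] on a symbol match; otherwise
    1 + min(previous[j], previous[j-1], chain) where chain collapses the
    in-row horizontal dependency through the last occurrence of the
    pattern symbol: previous[x-1] + (j-1-x) with x = occ row value, or
    i+j-1 when the symbol has no occurrence up to column j.

    Returns the full matrix when keep_matrix, else a 1-row matrix
    holding the final row.
    """
    n = t.shape[0]
    m = p.shape[0]
    if keep_matrix:
        D = np.zeros((m + 1, n + 1), dtype=np.int32)
    else:
        D = np.zeros((1, n + 1), dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    cur = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        r = sym_row[i - 1]
        cur[0] = i
        for j in range(1, n + 1):
            if t[j - 1] == p[i - 1]:
                cur[j] = prev[j - 1]
            else:
                x = occ[r, j]
                best = prev[j]
                if prev[j - 1] < best:
                    best = prev[j - 1]
                if x == 0:
                    chain = i + j - 1
                else:
                    chain = prev[x - 1] + (j - 1 - x)
                if chain < best:
                    best = chain
                cur[j] = 1 + best
        if keep_matrix:
            D[i, :] = cur
        prev, cur = cur, prev
    if not keep_matrix:
        D[0, :] = prev
    return D


@njit(cache=False)
def warp_kernel(t, p, occ, sym_row, w, keep_matrix):
    """Lane-register simulation of the warp-shuffle engine.

    Columns 0..n are partitioned into warps of ``w`` consecutive lanes.
    ``dvar`` models the per-lane register holding the lane's current
    cell; ``row_store`` models the device-memory copy of the previous
    row.  Per row each lane obtains its upper-left input via a shuffle
    from the lane below, except warp-boundary lanes (j % w == 0), which
    fall back to a memory read; the upper input is its own register; the
    chain input is always a memory read since it reaches an arbitrary
    column of the previous row.  Counters record every modeled access.

    Returns (matrix-or-final-row, counters).
    """
    n = t.shape[0]
    m = p.shape[0]
    if keep_matrix:
        D = np.zeros((m + 1, n + 1), dtype=np.int32)
    else:
        D = np.zeros((1, n + 1), dtype=np.int32)
    ctr = np.zeros(N_COUNTERS, dtype=np.int64)
    row_store = np.zeros(n + 1, dtype=np.int32)  # modeled memory: row i-1
    dvar = np.zeros(n + 1, dtype=np.int32)       # per-lane register D[i-1, j]
    new_dvar = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        r = sym_row[i - 1]
        for j in range(n + 1):
            if j == 0:
                d = i  # boundary column: no inputs consumed
            else:
                # T[j-1] and P[i-1] live in the modeled shared memory
                # (per-block substring + pattern cache).
                ctr[CTR_SHARED_READS] += 2
                if j % w == 0:
                    # leftmost lane of a warp: the lane below is in the
                    # neighbouring warp, shuffle cannot cross -> memory
                    avar = row_store[j - 1]
                    ctr[CTR_D_READS] += 1
                else:
                    avar = dvar[j - 1]  # __shfl_up(Dvar, 1)
                    ctr[CTR_SHUFFLES] += 1
                bvar = dvar[j]  # own register, no access
                x = occ[r, j]
                ctr[CTR_X_READS] += 1
                # chain input D[i-1, x-1] from modeled memory
                ctr[CTR_D_READS] += 1
                if t[j - 1] == p[i - 1]:
                    d = avar
                elif x == 0:
                    best = avar
                    if bvar < best:
                        best = bvar
                    if i + j - 1 < best:
                        best = i + j - 1
                    d = 1 + best
                else:
                    cvar = row_store[x - 1]
                    best = avar
                    if bvar < best:
                        best = bvar
                    if cvar + (j - 1 - x) < best:
                        best = cvar + (j - 1 - x)
                    d = 1 + best
            new_dvar[j] = d
        # write-back: every lane stores Dvar so chain reads in the next
        # row can reach arbitrary columns
        for j in range(n + 1):
            row_store[j] = new_dvar[j]
            ctr[CTR_WRITES] += 1
        dvar, new_dvar = new_dvar, dvar
        ctr[CTR_SYNCS] += 1  # row barrier
        if keep_matrix:
            D[i, :] = dvar
    if not keep_matrix:
        D[0, :] = dvar
    return D, ctr
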