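"""Dataflow simulator of the warp-shuffle engine, with access accounting.

The row-wise recurrence is mapped onto GPU-style warps: columns 0..n of
the grid are partitioned into warps of ``w`` consecutive lanes, one lane
per column, and each lane keeps its current cell in a register (Dvar).
Per row, a lane needs three inputs from the previous row:

* upper-left D[i-1, j-1] (Avar) — held by the lane below, so it arrives
  through a register shuffle.  A shuffle cannot cross a warp boundary,
  so lanes at columns with j % w == 0 read it from the modeled row
  store in memory instead;
* upper D[i-1, j] (Bvar) — the lane's own register, no access at all;
* chain input D[i-1, X[l,j]-1] (Cvar) — an arbitrary column of the
  previous row, always a memory read (and the reason every lane writes
  its register back to the row store after each row).

The simulator reproduces the oracle grid exactly for every warp width
and counts each modeled access, substantiating the traffic argument:
per interior cell the row-wise engine pays 3 previous-row reads, the
warp engine about 1 + 1/w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .row_parallel import pattern_occ_rows
from .sequences import DNA, Alphabet

__all__ = [
    "WarpConfig",
    "OpCounters",
    "shfl_up",
    "run_warp_sim",
    "predicted_counters",
    "dependency_replay_reads",
    "write_counters",
]


@dataclass(frozen=True)
class WarpConfig:
    """Warp width ``w``: lanes per warp, indexed 0..w-1.  Default 32."""

    w: int = 32

    def __post_init__(self) -> None:
        if self.w < 2:
            raise ValueError("warp width must be >= 2")


@dataclass(frozen=True)
class OpCounters:
    """Deterministic per-run counts of modeled accesses.

    ``mem_reads_dmat`` are previous-row reads (boundary upper-left
    fetches plus chain fetches); ``mem_reads_index`` are last-occurrence
    table reads; together they form the modeled global-memory reads.
    ``mem_reads_shared`` are text/pattern symbol reads, labeled shared
    for the per-block substring-and-pattern cache.  ``syncs`` counts row
    barriers.
    """

    mem_reads_dmat: int
    mem_reads_index: int
    mem_reads_shared: int
    mem_writes: int
    shuffles: int
    syncs: int
    w: int
    n: int
    m: int

    @property
    def mem_reads_global(self) -> int:
        return self.mem_reads_dmat + self.mem_reads_index

    @property
    def mem_reads(self) -> int:
        return self.mem_reads_global + self.mem_reads_shared


def shfl_up(values, delta: int) -> np.ndarray:
    """Register exchange within one warp: lane x receives lane x-delta.

    Lanes with lane_id < delta retain their own value; callers must not
    rely on those lanes (in the engine they take the memory fallback).
    """
    values = np.asarray(values)
    w = values.shape[0]
    if not 1 <= delta < w:
        raise ValueError(f"delta must be in [1, {w - 1}], got {delta}")
    out = values.copy()
    out[delta:] = values[: w - delta]
    return out


def _counters_from_vector(ctr: np.ndarray, w: int, n: int, m: int) -> OpCounters:
    return OpCounters(
        mem_reads_dmat=int(ctr[K.CTR_D_READS]),
        mem_reads_index=int(ctr[K.CTR_X_READS]),
        mem_reads_shared=int(ctr[K.CTR_SHARED_READS]),
        mem_writes=int(ctr[K.CTR_WRITES]),
        shuffles=int(ctr[K.CTR_SHUFFLES]),
        syncs=int(ctr[K.CTR_SYNCS]),
        w=w,
        n=n,
        m=m,
    )


def run_warp_sim(
    text,
    pattern,
    config: WarpConfig = WarpConfig(),
    *,
    keep_matrix: bool = False,
    alphabet: Alphabet = DNA,
) -> tuple[np.ndarray, OpCounters]:
    """Simulate the warp engine; distances are identical for every w.

    Returns ``(grid_or_final_row, counters)``.
    """
    t, p, occ, sym_row = pattern_occ_rows(text, pattern, alphabet)
    out, ctr = K.warp_kernel(t, p, occ, sym_row, config.w, keep_matrix)
    counters = _counters_from_vector(ctr, config.w, t.shape[0], p.shape[0])
    return (out if keep_matrix else out[0]), counters


def predicted_counters(n: int, m: int, w: int) -> OpCounters:
    """Closed-form access counts for a run on sizes (n, m, w).

    Per row: ``n - floor(n/w)`` shuffles (interior columns j in [1, n]
    with j % w != 0), ``n + floor(n/w)`` previous-row reads (one chain
    fetch per interior column plus one boundary upper-left fetch per
    warp start), ``n`` occurrence-table reads, ``2n`` cached symbol
    reads, ``n + 1`` write-backs, one barrier.  Counts are
    data-independent; the simulator's event counters must match these
    exactly.
    """
    if n < 0 or m < 0:
        raise ValueError("n and m must be non-negative")
    if w < 2:
        raise ValueError("warp width must be >= 2")
    boundary = n // w  # columns w, 2w, ... <= n
    return OpCounters(
        mem_reads_dmat=m * (n + boundary),
        mem_reads_index=m * n,
        mem_reads_shared=2 * m * n,
        mem_writes=m * (n + 1),
        shuffles=m * (n - boundary),
        syncs=m,
        w=w,
        n=n,
        m=m,
    )


def dependency_replay_reads(n: int, m: int) -> int:
    """Previous-row reads of a memory-only replay of the row-wise engine.

    Without shuffles or registers, each interior cell reads
    D[i-1, j-1], D[i-1, j] and the chain cell from memory: 3 per cell.
    """
    return 3 * m * n


def write_counters(counters: OpCounters, path) -> None:
    """Export counters as deterministic ``key=value`` lines."""
    keys = [
        "mem_reads_global",
        "mem_reads_shared",
        "mem_writes",
        "shuffles",
        "syncs",
        "w",
        "n",
        "m",
    ]
    with open(path, "w") as fh:
        for key in keys:
            fh.write(f"{key}={getattr(counters, key)}\n")
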