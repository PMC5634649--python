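"""Top-level search: one entry point, three interchangeable engines."""

from __future__ import annotations

import logging

from .dp_oracle import edit_distance_final_row, extract_matches
from .row_parallel import run_row_parallel
from .sequences import DNA, Alphabet, MatchReport, Sequence
from .warp_sim import WarpConfig, run_warp_sim

__all__ = ["search", "ENGINES"]

ENGINES = ("oracle", "rowparallel", "warpsim")

logger = logging.getLogger("kdiffasm")


def search(
    text: Sequence,
    pattern: Sequence,
    k: int,
    engine: str = "oracle",
    *,
    warp_width: int = 32,
    alphabet: Alphabet = DNA,
) -> MatchReport:
    """All 0-based text offsets where a factor ends within k edits.

    The three engines compute the same distances by construction; the
    report's entries are identical whichever is chosen.  The usual
    problem regime is n > m > k; anything else is legal (the recurrence
    is well defined) but logged as a warning since the results are
    rarely what one wants — e.g. with k >= m every position matches.
    """
    if len(pattern) < 1:
        raise ValueError("pattern must have length >= 1")
    if k < 0:
        raise ValueError("threshold k must be non-negative")
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    n, m = len(text), len(pattern)
    if not (n > m > k):
        logger.warning(
            "atypical problem shape: expected n > m > k, got n=%d m=%d k=%d", n, m, k
        )

    counters = None
    if engine == "oracle":
        final_row = edit_distance_final_row(text, pattern, alphabet)
    elif engine == "rowparallel":
        final_row = run_row_parallel(text, pattern, alphabet=alphabet)
    else:
        if warp_width < 2:
            raise ValueError("warp_width must be >= 2 for the warpsim engine")
        final_row, counters = run_warp_sim(
            text, pattern, WarpConfig(warp_width), alphabet=alphabet
        )

    return MatchReport(
        record_id=text.id,
        entries=extract_matches(final_row, k),
        k=k,
        engine=engine,
        counters=counters,
    )
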