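# Methods

## Problem and model

Given a text `T[0..n-1]` over an alphabet Σ (DNA `{A,C,G,T}` by
default), a pattern `P[0..m-1]` and a threshold `k`, the package
reports every 0-based offset `j` at which some factor of `T` ends whose
Levenshtein distance (insertions, deletions, substitutions; no
transpositions) to `P` is at most `k`. The underlying object is the
semi-global grid `D` with `D[0, j] = 0` and `D[i, 0] = i`:
`D[i, j]` is the minimum distance between `P[0..i-1]` and any factor of
`T` ending at (1-based) column `j`. Hits are the columns `j+1` of the
final row with value ≤ k; internally the hit set is also available in
the conventional sentinel encoding (`result[j] = j` for a hit, −1
otherwise).

The usual problem regime is `n > m > k`. Other shapes are legal — the
recurrence is well defined for every `n, m ≥ 0` — but are logged as
warnings, since e.g. `k ≥ m` matches every position (deleting the whole
pattern costs `m`). Nothing is ever silently truncated.

A note on semantics: a strict reading of "factors of length m within
k edits" differs from what the grid computes (factors of *any* length
ending at a column). The hit rule `D[m, j] ≤ k` is the standard one for
this family of algorithms and is what all engines and the reporting
layer implement; the two definitions coincide on which end positions
are within threshold up to factor-length bookkeeping that the output
does not expose.

## Dependency elimination

The classic recurrence couples `D[i, j]` to `D[i, j-1]` in the same
row. The row-parallel engine removes that coupling with a
last-occurrence index: `X[l, j]` is the largest 1-based position
`p ≤ j` with `T[p-1] = Q[l]`, or 0. Positions inside `X` are kept
1-based so the recurrence terms `X[l,j] − 1` and `j − 1 − X[l,j]` read
literally; conversion to 0-based happens only at the sequence-access
boundary. The in-row dependency collapses into a chain term: match the
current pattern symbol at its last occurrence `x = X[l, j]`, then pay
one insertion per subsequent column, giving `D[i-1, x-1] + (j-1-x)`;
when the symbol has not occurred at all the chain degenerates to the
all-insertions path `i + j - 1`. The test suite does not take this
identity on faith: it asserts, cell by cell on random instances, that
the three-term minimum over the previous row reproduces the classic
grid, and separately that evaluating the columns of a row in reverse
order gives the same row (no output column reads another output
column).

By default the index is built only for the symbols actually present in
the pattern — observationally equivalent to a full-Σ build, since the
recurrence only ever reads rows of pattern symbols, at
`O(|unique(P)|·n)` memory instead of `O(|Σ|·n)`. A full build is
available (`restrict_to=None`, the default of `build_occurrence_index`;
the engines use the restricted form internally).

## Warp dataflow simulation and access accounting

The warp engine maps one lane per grid column, `w` consecutive lanes
per warp (default `w = 32`, any `w ≥ 2`). Registers per lane follow the
GPU formulation: `Dvar` holds the lane's current cell, and per row the
three previous-row inputs arrive as

* `Avar = D[i-1, j-1]`: a `shfl_up(Dvar, 1)` register exchange from the
  lane below. Shuffles cannot cross warp boundaries, so lanes at
  columns `j` with `j mod w = 0` read the value from the modeled row
  store instead. Column 0 is a boundary lane of the first warp but
  takes the `j = 0 → i` case and performs no read at all (`D[i-1, -1]`
  does not exist).
* `Bvar = D[i-1, j]`: the lane's own register — no access of any kind.
* `Cvar = D[i-1, X[l,j]-1]`: always a memory read, since the chain can
  reach an arbitrary column of the previous row. This is also why
  every lane writes `Dvar` back to the row store at the end of each
  row: the next row's chain reads must find a complete row in memory.

Rows are advanced synchronously behind a counted barrier; intra-row
lane scheduling is not modeled beyond the shuffle/boundary distinction,
because the dataflow has no other intra-row exchange. The memory
fallback condition is column-indexed (`j mod w = 0`): the lanes that
need it are exactly the leftmost lanes of warps, which partition the
columns, not the rows.

Accounting (all counts deterministic, data-independent, and matched
exactly by the closed form `predicted_counters(n, m, w)`):

| counter            | per row                  | meaning |
|--------------------|--------------------------|---------|
| `mem_reads_dmat`   | `n + ⌊n/w⌋`              | chain fetches (one per interior column) + boundary `Avar` fetches (one per warp start) |
| `mem_reads_index`  | `n`                      | occurrence-table lookups |
| `mem_reads_shared` | `2n`                     | text + pattern symbol reads |
| `mem_writes`       | `n + 1`                  | row-store write-backs |
| `shuffles`         | `n − ⌊n/w⌋`              | register exchanges |
| `syncs`            | `1`                      | row barrier |

Text and pattern reads are labeled *shared* to model the per-block
substring-and-pattern cache of the GPU implementation; grid and index
reads are labeled *global*. The label is the cache's entire testable
effect — no timing model is attached, and no hardware throughput claim
is made. The measurable claim is the traffic one: a memory-only replay
of the row engine reads 3 previous-row cells per interior cell
(`3mn`), the warp engine `m(n + ⌊n/w⌋)`, a ratio approaching
`(1 + 1/w)/3` — about one third fewer reads already at `w = 2`, and
0.344 at `w = 32`. The simulator's counters are compared against both
the closed form and the replay bound in the tests and the acceptance
script.

## Symbols outside the alphabet

Case is folded on input by default. Symbols outside the declared
alphabet (e.g. `N`, IUPAC ambiguity codes) are retained but are
*universal mismatches*: they never compare equal to any pattern symbol,
not even to an identical character. Internally, out-of-alphabet text
and pattern symbols receive distinct sentinel codes, so the property
holds uniformly in all three engines; a pattern symbol outside the
alphabet simply has an all-zero occurrence row (it never occurs in the
encoded text), which keeps the dependency-eliminated recurrence exact
without a special case. `global_edit_distance`, by contrast, is a
property of two strings alone and uses plain symbol identity.

## Synthetic data

`random_dna` draws i.i.d. uniform symbols; `plant_occurrence` applies
exactly `edits` operations (uniform over the feasible subset of
insertion/deletion/substitution) to a copy of the pattern and splices
it into the text by overwriting, keeping the text length fixed.
Insertions are restricted to interior positions: an insertion at either
end would ambiguously extend the factor into the surrounding text and
make the recorded end position ill-defined. `edits` is an upper bound
on the factor's true distance (operations can cancel — a substitution
may redraw the same base), so every guarantee is stated with ≤, never
=. The defaults exercised in tests and the acceptance script mirror the
benchmark regime the engines target: 10 kb texts, pattern length 16,
k = 6, edit budgets 0–6, 100 seeded trials.

What the generator does *not* emulate: realistic genome composition
(GC skew, repeats, homopolymers), sequencing-error profiles, or
multi-record texts with boundary effects. Passing the planted-recovery
tests shows the engines find what was planted under uniform background;
it says nothing about match *density* in real genomes, which is
composition-dependent.

## Numerical and design choices

* Grid cells are exact small integers (`int32`; values never exceed
  `m`). There is no floating point anywhere in the recurrences.
* Ties in the three-term minimum are value-ties only; no tie-breaking
  policy can affect any output.
* All engines expose a final-row-only mode with `O(n)` working memory
  (two-row rolling buffer); full grids are materialised only on
  request (`keep_matrix=True`).
* Inner loops are compiled with numba; the public row operations
  (`compute_row`, `shfl_up`) are plain numpy reference forms used by
  the order-independence and shuffle-semantics tests.
* Degenerate inputs: an empty pattern yields the all-zero row (every
  position matches at distance 0 for any k ≥ 0); an empty text yields
  the single column `0..m`. `search` itself requires `m ≥ 1`.
* Problem sizes in the standard checks — exhaustive equivalence over
  the binary alphabet up to `n = 12, m = 5` plus 500 random instances
  up to `n = 200, m = 30`; 100 brute-force comparisons up to
  `n = 40, m = 8`; 50 counter-model triples up to `n = 1000` — were
  chosen so the full suite completes in about a minute while covering
  every boundary case class (warp boundaries at every `j mod w`,
  absent symbols, chain degeneracy, empty prefixes).

## Known limitations

* Distances only: no alignment traceback, so reported matches carry an
  end position but no start position. BED output therefore marks
  single-base endpoints.
* One pattern per search; no multi-pattern dictionary, no banded or
  bit-parallel acceleration (the row/warp formulations, not raw speed,
  are the point of this package).
* The warp simulator models dataflow and access counts, not time: no
  occupancy, latency or block-size effects, and no claim about actual
  GPU throughput.
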