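# kdiffasm

Approximate string matching with *k* differences over DNA texts: find
every position of a text `T[0..n-1]` at which some factor (substring)
ends whose Levenshtein distance to a pattern `P[0..m-1]` is at most a
threshold *k*. The package is for people studying or teaching the
parallelisation of this classic problem: alongside the textbook
dynamic program it implements a dependency-eliminated row-wise
recurrence and a faithful *dataflow simulation* of that recurrence
mapped onto GPU-style warps with register shuffles — including exact
accounting of every modeled memory access, so the memory-traffic
advantage of the warp formulation can be measured without any GPU.

## The three engines

All engines compute the semi-global edit-distance grid `D` of shape
`(m+1) × (n+1)`:

```
D[0, j] = 0                      (a match may start anywhere)
D[i, 0] = i
D[i, j] = D[i-1, j-1]                                if T[j-1] = P[i-1]
        = 1 + min(D[i-1,j], D[i,j-1], D[i-1,j-1])    otherwise
```

`D[m, j] ≤ k` marks a hit ending at text offset `j-1` (0-based).

* **oracle** — the sequential recurrence above; the ground truth.
* **rowparallel** — eliminates the in-row dependency `D[i, j-1]` using
  a last-occurrence index `X` of the text (`X[l, j]` = last position
  `≤ j` where symbol `Q[l]` occurs, 0 if none):

  ```
  D[i, j] = 1 + min(D[i-1,j], D[i-1,j-1], i+j-1)                     if X[l,j] = 0
          = 1 + min(D[i-1,j], D[i-1,j-1], D[i-1,X[l,j]-1] + j-1-X[l,j])  otherwise
  ```

  (`l` indexes `P[i-1]`). Every column of a row now depends on the
  previous row only, so an entire row can be computed in parallel.
* **warpsim** — simulates mapping one lane (thread) per grid column,
  in warps of `w` lanes. Per row a lane gets its upper-left input by a
  register shuffle from the lane below (warp-boundary lanes fall back
  to a memory read), keeps its upper input in its own register, and
  reads only the last-occurrence chain cell from memory. The simulator
  counts reads, writes, shuffles and barriers: per interior cell the
  row engine pays 3 previous-row reads, the warp engine `1 + 1/w`.

The three engines return identical match reports on every input; the
test suite asserts this exhaustively on small instances and on seeded
random ones, and checks the oracle itself against brute-force factor
enumeration scored by `edlib`.

## Worked example

```python
>>> from kdiffasm import Sequence, search
>>> text = Sequence("example", "CATGACTG")
>>> search(text, Sequence("p", "TACTG"), k=2, engine="warpsim").entries
[(3, 2), (6, 2), (7, 1)]
```

Factors ending at 0-based offsets 3, 6 and 7 of `CATGACTG` are within
2 edits of `TACTG` (distances 2, 2 and 1: e.g. the suffix `ACTG` is one
deletion away from the pattern). The same instance from the shell:

```
$ kdiffasm search --text text.fa --pattern TACTG -k 2 \
      --engine warpsim --warp-width 4 --out hits.tsv --counters ctr.txt
example: 3 matches (k=2, engine=warpsim)
$ cat ctr.txt
mem_reads_global=90
mem_reads_shared=80
mem_writes=45
shuffles=30
syncs=5
w=4
n=8
m=5
```

With 9 grid columns in warps of 4, each of the 5 pattern rows performs
6 shuffles (interior columns 1–8 minus warp-boundary columns 4 and 8),
10 previous-row reads (8 chain fetches + 2 boundary fetches) plus 8
occurrence-table reads, and writes all 9 cells back — exactly what the
closed-form model `predicted_counters(8, 5, 4)` gives.

Synthetic benchmarks with planted approximate occurrences:

```
$ kdiffasm synth --length 10000 --pattern ACGTACGTACGTACGT --plant 5 \
      --edits 3 --seed 7 --out-fasta t.fa --out-truth truth.tsv
wrote 10000 bp with 5 planted occurrences (3 edits each) to t.fa
```

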