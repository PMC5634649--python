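"""Dependency-eliminated engine: per-row recurrence and oracle equivalence."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kdiffasm import (
    build_occurrence_index,
    compute_row,
    edit_distance_matrix,
    run_row_parallel,
)


def matches_vector(text: str, symbol: str) -> np.ndarray:
    """matches[j] <=> text[j-1] == symbol, j >= 1 (position 0 unused)."""
    out = np.zeros(len(text) + 1, dtype=bool)
    for j in range(1, len(text) + 1):
        out[j] = text[j - 1] == symbol
    return out


def scalar_cell(previous, i, j, matches, occ_row):
    """One output column evaluated in isolation (order-independence probe)."""
    if j == 0:
        return i
    if matches[j]:
        return int(previous[j - 1])
    x = int(occ_row[j])
    chain = i + j - 1 if x == 0 else int(previous[x - 1]) + (j - 1 - x)
    return 1 + min(int(previous[j]), int(previous[j - 1]), chain)


class TestComputeRow:
    def test_worked_example_row5_column7(self):
        # Row 5 handles pattern symbol G; its last occurrence before
        # column 7 is at position 4, giving chain previous[3] + 2.
        text = "CATGACTG"
        idx = build_occurrence_index(text)
        previous = np.array([4, 3, 3, 2, 3, 3, 2, 1, 2], dtype=np.int32)
        row = compute_row(previous, 5, matches_vector(text, "G"), idx.row("G"))
        assert row[7] == 2
        assert row.tolist() == edit_distance_matrix(text, "TACTG")[5].tolist()

    def test_worked_example_row1_column1(self):
        # Pattern symbol T has no occurrence up to column 1, so the
        # chain term degenerates to i + j - 1.
        text = "CATGACTG"
        idx = build_occurrence_index(text)
        previous = np.zeros(9, dtype=np.int32)
        row = compute_row(previous, 1, matches_vector(text, "T"), idx.row("T"))
        assert row[1] == 1
        assert row.tolist() == edit_distance_matrix(text, "T")[1].tolist()

    def test_column_zero_is_row_index(self):
        idx = build_occurrence_index("ACGT")
        row = compute_row(np.zeros(5, dtype=np.int32), 3,
                          matches_vector("ACGT", "A"), idx.row("A"))
        assert row[0] == 3

    def test_row_index_out_of_range_rejected(self):
        idx = build_occurrence_index("ACGT")
        with pytest.raises(ValueError):
            compute_row(np.zeros(5, dtype=np.int32), 0,
                        matches_vector("ACGT", "A"), idx.row("A"))

    def test_column_order_independence(self, rng):
        # Evaluating columns one by one in reverse order must reproduce
        # the forward row: no output column reads another output column.
        for _ in range(20):
            n = int(rng.integers(1, 60))
            text = "".join(rng.choice(list("ACGT"), size=n))
            pattern = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 9))))
            D = edit_distance_matrix(text, pattern)
            idx = build_occurrence_index(text)
            i = int(rng.integers(1, len(pattern) + 1))
            sym = pattern[i - 1]
            matches = matches_vector(text, sym)
            forward = compute_row(D[i - 1], i, matches, idx.row(sym))
            reverse = [scalar_cell(D[i - 1], i, j, matches, idx.row(sym))
                       for j in reversed(range(n + 1))][::-1]
            assert forward.tolist() == reverse
            assert forward.tolist() == D[i].tolist()


class TestChainCollapse:
    def test_eliminated_recurrence_holds_on_oracle_grid(self, rng):
        # The single-row form must be an identity over the classic grid:
        # for every non-match cell, the three-term minimum over the
        # previous row (with the last-occurrence chain standing in for
        # the in-row horizontal dependency) reproduces the cell.
        for _ in range(30):
            n = int(rng.integers(1, 40))
            text = "".join(rng.choice(list("ACGT"), size=n))
            pattern = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
            D = edit_distance_matrix(text, pattern)
            idx = build_occurrence_index(text)
            for i in range(1, len(pattern) + 1):
                occ = idx.row(pattern[i - 1])
                for j in range(1, n + 1):
                    if text[j - 1] == pattern[i - 1]:
                        assert D[i, j] == D[i - 1, j - 1]
                        continue
                    x = int(occ[j])
                    chain = i + j - 1 if x == 0 else int(D[i - 1, x - 1]) + (j - 1 - x)
                    assert D[i, j] == 1 + min(int(D[i - 1, j]),
                                              int(D[i - 1, j - 1]), chain)


class TestEngineEquivalence:
    def test_exhaustive_small_binary_alphabet(self):
        for n in range(1, 9):
            for tt in itertools.product("AC", repeat=n):
                text = "".join(tt)
                for m in range(1, 5):
                    for pp in itertools.product("AC", repeat=m):
                        pattern = "".join(pp)
                        assert np.array_equal(
                            run_row_parallel(text, pattern, keep_matrix=True),
                            edit_distance_matrix(text, pattern),
                        )

    @given(st.text(alphabet="ACGT", min_size=1, max_size=200),
           st.text(alphabet="ACGT", min_size=1, max_size=30))
    def test_random_instances_match_oracle(self, text, pattern):
        assert np.array_equal(
            run_row_parallel(text, pattern, keep_matrix=True),
            edit_distance_matrix(text, pattern),
        )

    def test_final_row_mode(self, example):
        full = run_row_parallel(example.text, example.pattern, keep_matrix=True)
        row = run_row_parallel(example.text, example.pattern)
        assert np.array_equal(row, full[-1])
        assert row.tolist() == [5, 4, 4, 3, 2, 3, 3, 2, 1]

    def test_empty_pattern_zero_row(self):
        assert run_row_parallel("ACGT", "").tolist() == [0] * 5

    def test_pattern_with_unknown_symbols_matches_oracle(self):
        # N never matches anything, including a text N.
        text, pattern = "ACGNNACGT", "ANG"
        assert np.array_equal(
            run_row_parallel(text, pattern, keep_matrix=True),
            edit_distance_matrix(text, pattern),
        )
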