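"""Seeded synthetic DNA with planted approximate pattern occurrences.

The generator emulates the benchmark regime the engines are meant for:
uniform random text over {A, C, G, T}, patterns around length 16, and a
difference budget k up to 6, with occurrences planted by applying a
known number of edits to the pattern and splicing the result into the
text.  ``edits`` is an upper bound on the true edit distance of the
planted factor (operations may cancel), so the recovery guarantee is
stated with <=, never =.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dp_oracle import edit_distance_matrix, extract_matches, global_edit_distance, result_array
from .sequences import DNA, Alphabet, Sequence

__all__ = [
    "PlantedTruth",
    "WorkedExample",
    "random_dna",
    "plant_occurrence",
    "synthesize",
    "worked_example",
    "write_fasta",
    "write_truth",
]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted occurrence.

    ``end_position`` is the 0-based inclusive offset of the planted
    factor's last symbol in the mutated text; the factor's true edit
    distance to the pattern is at most ``planted_edits``.
    """

    end_position: int
    planted_edits: int
    mutated_factor: str


@dataclass(frozen=True)
class WorkedExample:
    """The eight-symbol demonstration instance with derived expectations."""

    text: Sequence
    pattern: Sequence
    k: int
    end_positions: tuple[int, ...]
    entries: tuple[tuple[int, int], ...]
    final_row: tuple[int, ...]
    result: tuple[int, ...]


def random_dna(length: int, seed, alphabet: Alphabet = DNA, *, id: str = "synthetic") -> Sequence:
    """Uniform i.i.d. random sequence; deterministic for a fixed seed."""
    if length < 0:
        raise ValueError("length must be non-negative")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(alphabet), size=length)
    symbols = "".join(alphabet.symbols[d] for d in draws)
    return Sequence(id=id, symbols=symbols)


def _mutate(pattern: str, edits: int, rng: np.random.Generator, alphabet: Alphabet) -> str:
    """Apply exactly ``edits`` random edit operations to ``pattern``.

    Insertions are restricted to interior positions so the mutated
    factor's boundaries stay well defined (an insertion at either end
    would ambiguously extend the factor into the surrounding text).
    """
    s = list(pattern)
    for _ in range(edits):
        ops = ["sub"] if len(s) >= 1 else []
        if len(s) >= 2:
            ops += ["ins", "del"]
        if not ops:
            raise ValueError("cannot edit an empty factor")
        op = ops[int(rng.integers(0, len(ops)))]
        if op == "sub":
            i = int(rng.integers(0, len(s)))
            s[i] = alphabet.symbols[int(rng.integers(0, len(alphabet)))]
        elif op == "ins":
            i = int(rng.integers(1, len(s)))  # interior gap, never an end
            s.insert(i, alphabet.symbols[int(rng.integers(0, len(alphabet)))])
        else:
            i = int(rng.integers(0, len(s)))
            del s[i]
    return "".join(s)


def plant_occurrence(
    text: Sequence,
    pattern: Sequence,
    edits: int,
    position: int,
    seed,
    alphabet: Alphabet = DNA,
) -> tuple[Sequence, PlantedTruth]:
    """Splice a mutated copy of the pattern into the text at ``position``.

    The mutated factor overwrites the text segment starting at the
    0-based ``position``; the text keeps its length.  The returned
    truth record satisfies
    ``global_edit_distance(mutated_factor, pattern) <= edits``, so a
    search with any threshold k >= edits must report ``end_position``.
    """
    if edits < 0:
        raise ValueError("edits must be non-negative")
    rng = np.random.default_rng(seed)
    factor = _mutate(pattern.symbols, edits, rng, alphabet)
    end = position + len(factor)
    if position < 0 or end > len(text):
        raise ValueError(
            f"cannot splice a {len(factor)}-symbol factor at position {position} "
            f"into a text of length {len(text)}"
        )
    mutated = text.symbols[:position] + factor + text.symbols[end:]
    truth = PlantedTruth(
        end_position=end - 1, planted_edits=edits, mutated_factor=factor
    )
    assert global_edit_distance(factor, pattern) <= edits
    return Sequence(id=text.id, symbols=mutated), truth


def synthesize(
    length: int,
    pattern: Sequence,
    n_plants: int,
    edits: int,
    seed,
    alphabet: Alphabet = DNA,
) -> tuple[Sequence, list[PlantedTruth]]:
    """A random text with ``n_plants`` non-overlapping planted occurrences.

    The text is divided into equal slots, one plant per slot at a
    random in-slot offset, so planted factors never overlap.
    """
    rng = np.random.default_rng(seed)
    text = random_dna(length, rng, alphabet, id=f"synth_L{length}_seed{seed}")
    if n_plants == 0:
        return text, []
    slot = length // n_plants
    margin = len(pattern) + edits  # worst-case factor length
    if slot < margin:
        raise ValueError(
            f"text of length {length} cannot hold {n_plants} non-overlapping "
            f"occurrences of a {len(pattern)}-symbol pattern with {edits} edits"
        )
    truths = []
    for p in range(n_plants):
        offset = int(rng.integers(0, slot - margin + 1))
        text, truth = plant_occurrence(
            text, pattern, edits, p * slot + offset, rng, alphabet
        )
        truths.append(truth)
    return text, truths


def worked_example() -> WorkedExample:
    """The standard eight-symbol demonstration instance.

    Text CATGACTG, pattern TACTG, threshold 2; expectations are derived
    by running the reference engine, not hard-coded.
    """
    text = Sequence(id="example", symbols="CATGACTG")
    pattern = Sequence(id="pattern", symbols="TACTG")
    k = 2
    final_row = edit_distance_matrix(text, pattern)[len(pattern)]
    entries = tuple(extract_matches(final_row, k))
    return WorkedExample(
        text=text,
        pattern=pattern,
        k=k,
        end_positions=tuple(e for e, _ in entries),
        entries=entries,
        final_row=tuple(int(v) for v in final_row),
        result=tuple(int(v) for v in result_array(final_row, k)),
    )


def write_fasta(seq: Sequence, path, *, width: int = 60) -> None:
    """Write one record; fixed line width keeps the bytes deterministic."""
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n")
        for i in range(0, len(seq), width):
            fh.write(seq.symbols[i : i + width] + "\n")


def write_truth(truths: list[PlantedTruth], path) -> None:
    """Truth table TSV: end_position, planted_edits, mutated_factor."""
    with open(path, "w") as fh:
        fh.write("end_position\tplanted_edits\tmutated_factor\n")
        for t in truths:
            fh.write(f"{t.end_position}\t{t.planted_edits}\t{t.mutated_factor}\n")
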