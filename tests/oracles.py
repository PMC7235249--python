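"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and vectorization) of the package:
the alignment oracle scores by exhaustive recursion over edit operations, the
protospacer oracle slides a window in pure Python, and the dinucleotide
oracle tallies with a Counter.
"""

from __future__ import annotations

import math
from collections import Counter
from functools import lru_cache

from Bio.Align import substitution_matrices

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_align_score(a: str, b: str, matrix_name: str = "BLOSUM62",
                      gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal global alignment score by recursion over all alignments.

    Affine gaps: a gap of length L costs gap_open + L * gap_extend, terminal
    gaps included. State tracks whether the previous column was a gap so
    extension is charged correctly.
    """
    m = substitution_matrices.load(matrix_name)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 = last column was a pair, 1 = gap in b (a consumed),
        # 2 = gap in a (b consumed)
        if i == len(a) and j == len(b):
            return 0.0
        out = -math.inf
        if i < len(a) and j < len(b):
            out = max(out, m[a[i], b[j]] + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            out = max(out, -cost + best(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            out = max(out, -cost + best(i, j + 1, 2))
        return out

    return best(0, 0, 0)


def brute_protospacer_hits(spacer: str, genome: str,
                           max_mismatches: int) -> set[tuple[int, int, str, int]]:
    """Every (start, end, strand, mismatches) where the spacer matches,
    by checking each offset on each strand one base at a time."""
    hits = set()
    k = len(spacer)
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        for start in range(len(genome) - k + 1):
            mm = sum(1 for x, y in zip(genome[start:start + k], query) if x != y)
            if mm <= max_mismatches:
                hits.add((start, start + k, strand, mm))
    return hits


def brute_dinucleotide_counts(seq: str) -> tuple[Counter, int]:
    """Overlapping dinucleotide tally skipping windows containing N."""
    counts: Counter = Counter()
    for i in range(len(seq) - 1):
        window = seq[i:i + 2]
        if "N" not in window:
            counts[window] += 1
    return counts, sum(counts.values())


def brute_motif_window_match(window: str, motif: str,
                             iupac: dict[str, frozenset]) -> bool:
    return all(b in iupac[c] for b, c in zip(window, motif))
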