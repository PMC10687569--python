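"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration, without
touching the library's implementations, so that implementation and oracle
can only agree by both being correct.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Align import substitution_matrices
from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# Exhaustive global-alignment enumeration (affine gaps)


def _enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as a list of column pairs,
    where a column is (char, char), (char, None) or (None, char)."""

    def rec(i, j, prefix):
        if i == len(a) and j == len(b):
            yield prefix
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, prefix + [(a[i], b[j])])
        if i < len(a):
            yield from rec(i + 1, j, prefix + [(a[i], None)])
        if j < len(b):
            yield from rec(i, j + 1, prefix + [(None, b[j])])

    yield from rec(0, 0, [])


def brute_force_align_score(
    a: str, b: str, matrix_name: str, gap_open: float, gap_extend: float
) -> float:
    """Max score over all global alignments; a gap run of length L in either
    sequence costs gap_open + (L-1)*gap_extend (terminal gaps included)."""
    matrix = substitution_matrices.load(matrix_name)
    best = float("-inf")
    for aln in _enumerate_alignments(a, b):
        score = 0.0
        prev_gap = None  # which sequence is currently in a gap run
        for ca, cb in aln:
            if ca is not None and cb is not None:
                score += matrix[ca, cb]
                prev_gap = None
            elif cb is None:  # gap in b
                score -= gap_extend if prev_gap == "b" else gap_open
                prev_gap = "b"
            else:  # gap in a
                score -= gap_extend if prev_gap == "a" else gap_open
                prev_gap = "a"
        best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# Brute-force NG86 (independent of hsp70census.molevo)

BASES = "ACGT"


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stop


def bf_synonymous_sites(codon: str) -> float:
    """Fraction of the nine single-base mutants that are synonymous."""
    aa = _aa(codon)
    assert aa != "*"
    count = 0
    for pos, base in itertools.product(range(3), BASES):
        if base == codon[pos]:
            continue
        if _aa(codon[:pos] + base + codon[pos + 1 :]) == aa:
            count += 1
    return count / 3


def bf_pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over minimal pathways, stop-passing paths excluded
    (all paths used if every one is blocked)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in itertools.permutations(diff):
        cur = ca
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*" or _aa(cur) == "*":
                hit_stop = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hit_stop else clean).append((sd, nd))
    paths = clean or blocked
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


SENSE_CODONS = [
    "".join(c)
    for c in itertools.product(BASES, repeat=3)
    if _aa("".join(c)) != "*"
]
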