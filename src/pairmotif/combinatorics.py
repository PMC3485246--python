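"""Closed-form machinery for pairwise Hamming-ball intersections.

Given two l-mers x, x' at Hamming distance h, the *candidate motifs*
shared by the pair are

    M_d(x, x') = { y : d_H(y, x) <= d  and  d_H(y, x') <= d },

the intersection of the two radius-d Hamming balls.  Each member y is
characterised, relative to the pair, by the signature

    (alpha, beta) = (|P10|, |P00|),

the number of agreeing positions where y matches neither word, and the
number of disagreeing positions where y matches neither word.  The set
of admissible signatures — the *mapping relation* R(x, x') — depends
only on (l, d, h), and within one signature the residual freedom is the
number k of disagreeing positions reset from x' to x's character.  From
d_H(y, x) = alpha + h - k and d_H(y, x') = alpha + beta + k the feasible
range of k is

    max(0, alpha + h - d)  <=  k  <=  min(h - beta, d - alpha - beta),

which yields both the relation and the exact cardinality

    |M_d(x, x')| = sum over (alpha, beta) in R of
        C(l-h, alpha) 3^alpha * C(h, beta) 2^beta * sum_k C(h - beta, k).

All counts use exact integer arithmetic (they overflow 64 bits for
large l).  The formula is validated in the test suite against exhaustive
enumeration of all 4^l words at small l.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .core import PMSParams

__all__ = [
    "PairRelation",
    "CandidateCountTable",
    "k_range",
    "mapping_relation",
    "candidate_count",
    "neighborhood_probability",
]


def k_range(params: PMSParams, h: int, alpha: int, beta: int) -> range:
    """Feasible values of k (positions reset to x's base) for one
    signature; empty when the signature is inadmissible."""
    lo = max(0, alpha + h - params.d)
    hi = min(h - beta, params.d - alpha - beta)
    return range(lo, hi + 1)


@dataclass(frozen=True)
class PairRelation:
    """The admissible (alpha, beta) signatures for a pair at distance h."""

    h: int
    tuples: tuple[tuple[int, int], ...]

    def __contains__(self, item: tuple[int, int]) -> bool:
        return item in self.tuples

    def __len__(self) -> int:
        return len(self.tuples)


def mapping_relation(params: PMSParams, h: int) -> PairRelation:
    """Compute R(x, x') for any pair at Hamming distance h.

    The relation is empty exactly when h > 2d; tuples are returned in
    lexicographic order.
    """
    l, d = params.l, params.d
    if not (0 <= h <= l):
        raise ValueError(f"h must be in [0, {l}], got {h}")
    tuples = tuple(
        (alpha, beta)
        for alpha in range(0, l - h + 1)
        for beta in range(0, h + 1)
        if len(k_range(params, h, alpha, beta)) > 0
    )
    return PairRelation(h=h, tuples=tuples)


def candidate_count(params: PMSParams, h: int) -> int:
    """Exact |M_d(x, x')| for any pair of l-mers at Hamming distance h."""
    l, d = params.l, params.d
    if not (0 <= h <= l):
        raise ValueError(f"h must be in [0, {l}], got {h}")
    total = 0
    for alpha, beta in mapping_relation(params, h).tuples:
        ways_k = sum(comb(h - beta, k) for k in k_range(params, h, alpha, beta))
        total += comb(l - h, alpha) * 3**alpha * comb(h, beta) * 2**beta * ways_k
    return total


class CandidateCountTable:
    """Per-h cache of |M_d| for h = 0..2d at fixed (l, d).

    Built once before a search so that reference-sequence selection can
    sum candidate volumes by table lookup.
    """

    def __init__(self, params: PMSParams):
        self.params = params
        top = min(2 * params.d, params.l)
        self._counts = tuple(candidate_count(params, h) for h in range(top + 1))

    def __getitem__(self, h: int) -> int:
        if 0 <= h < len(self._counts):
            return self._counts[h]
        if h <= self.params.l:
            return 0
        raise IndexError(f"h={h} exceeds word length {self.params.l}")

    def as_dict(self) -> dict[int, int]:
        return dict(enumerate(self._counts))


def neighborhood_probability(l: int, k: int) -> float:
    """Probability that two independent uniform-random l-mers lie within
    Hamming distance k of each other.

    This is the binomial tail p_k = sum_{i<=k} C(l, i) (3/4)^i (1/4)^(l-i),
    evaluated in exact rational arithmetic before conversion to float.
    Large values of p_{2d} mark "weak" (l, d) instances where spurious
    motifs abound.
    """
    if not (0 <= k <= l):
        raise ValueError(f"require 0 <= k <= l, got (l={l}, k={k})")
    total = sum(comb(l, i) * 3**i for i in range(k + 1))
    return float(Fraction(total, 4**l))
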