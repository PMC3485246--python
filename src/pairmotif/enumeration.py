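"""Deterministic traversal of a pair's candidate-motif set M_d(x, x').

Starting from y = x', every candidate is produced by a unique triple of
edits keyed to one (alpha, beta) signature of the mapping relation:

  1. pick ``alpha`` agreeing positions and set each to one of the three
     bases differing from x (hence from x');
  2. pick ``beta`` disagreeing positions and set each to one of the two
     bases differing from both x and x';
  3. pick ``k`` further disagreeing positions and reset each to x's
     base, with k ranging over the feasible interval for the signature.

Because the signature subsets of M_d(x, x') are mutually disjoint and
each (positions, characters, k) choice yields a distinct word, every
candidate appears exactly once.  Traversal order is fixed — signatures
in lexicographic order, then position subsets, character substitutions
and k in canonical ascending order — so runs are reproducible.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterator

from .combinatorics import k_range, mapping_relation
from .core import EncodedLmer, PMSParams, hamming_code

__all__ = ["enumerate_candidates", "iter_candidate_codes"]


def iter_candidate_codes(
    x_code: int, xp_code: int, params: PMSParams
) -> Iterator[int]:
    """Yield the packed codes of M_d(x, x'), each exactly once.

    Low-level engine behind :func:`enumerate_candidates`; works on raw
    integers so the search hot loop avoids object construction.
    """
    l, d = params.l, params.d
    h = hamming_code(x_code, xp_code)
    if h > 2 * d:
        return

    shifts = [2 * (l - 1 - i) for i in range(l)]
    xb = [(x_code >> s) & 3 for s in shifts]
    xpb = [(xp_code >> s) & 3 for s in shifts]
    p1 = [i for i in range(l) if xb[i] == xpb[i]]
    p0 = [i for i in range(l) if xb[i] != xpb[i]]

    clear = [3 << s for s in shifts]
    # step-1 choices: the three bases differing from x, pre-shifted
    alt3 = {i: [c << shifts[i] for c in range(4) if c != xb[i]] for i in p1}
    # step-2 choices: the two bases differing from both x and x'
    alt2 = {
        i: [c << shifts[i] for c in range(4) if c != xb[i] and c != xpb[i]]
        for i in p0
    }
    # step-3 edit: flip x' base to x base at a disagreeing position
    to_x_xor = {i: (xb[i] ^ xpb[i]) << shifts[i] for i in p0}

    base = xp_code
    for alpha, beta in mapping_relation(params, h).tuples:
        ks = list(k_range(params, h, alpha, beta))
        for apos in combinations(p1, alpha):
            a_clear = 0
            for i in apos:
                a_clear |= clear[i]
            a_base = base & ~a_clear
            for aset in product(*(alt3[i] for i in apos)):
                ya = a_base
                for bits in aset:
                    ya |= bits
                for bpos in combinations(p0, beta):
                    b_clear = 0
                    for i in bpos:
                        b_clear |= clear[i]
                    yb_base = ya & ~b_clear
                    rest = [i for i in p0 if i not in bpos]
                    for bset in product(*(alt2[i] for i in bpos)):
                        yb = yb_base
                        for bits in bset:
                            yb |= bits
                        for k in ks:
                            for kpos in combinations(rest, k):
                                yk = yb
                                for i in kpos:
                                    yk ^= to_x_xor[i]
                                yield yk


def enumerate_candidates(
    x: EncodedLmer, x_prime: EncodedLmer, params: PMSParams
) -> Iterator[EncodedLmer]:
    """Stream every candidate motif shared by (x, x'), each exactly once.

    The emitted set is exactly {y : d_H(y, x) <= d and d_H(y, x') <= d};
    a pair at distance greater than 2d yields an empty stream.  The
    degenerate pair x = x' walks the full radius-d ball around x through
    the same code path (beta and the signature's slack force k = 0).
    """
    if x.length != x_prime.length:
        raise ValueError(f"length mismatch: {x.length} != {x_prime.length}")
    if x.length != params.l:
        raise ValueError(f"word length {x.length} != params.l {params.l}")
    for code in iter_candidate_codes(x.code, x_prime.code, params):
        yield EncodedLmer(code=code, length=params.l)
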