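"""Exact planted (l, d) motif search driven by pairs of l-mers.

The search walks every l-mer x of the first sequence.  For each x a
*reference sequence* is chosen among the remaining sequences — the one
whose 2d-ball occurrences around x carry the smallest total candidate
volume (summed |M_d| over its qualifying windows, looked up in a
precomputed per-distance table).  Pairing x with each window x' of the
reference restricts the candidate space to the ball intersection
M_d(x, x'), whose members are streamed by the deterministic traversal
in :mod:`pairmotif.enumeration`.  Before verification, the windows of
every other sequence are filtered by two sound rules:

  Rule 1  discard z if d_H(z, x) > 2d or d_H(z, x') > 2d;
  Rule 2  discard z if no signature (alpha, beta) of the pair's mapping
          relation satisfies |p10(z) - alpha| + |p00(z) - beta| <= d.

Neither rule can discard a window lying within d of any member of
M_d(x, x') (a property the test suite checks exhaustively), so a
candidate y is a motif iff every filtered window list contains a word
within d of y; the first sequence and the reference need no re-check
because x and x' themselves witness them.

:func:`brute_force_search` is the definitional oracle: it scans all 4^l
patterns and keeps those with a window within d in every sequence.  It
is independent of the pair-driven machinery and exists for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .combinatorics import CandidateCountTable, PairRelation, mapping_relation
from .core import (
    BASE_TO_BITS,
    EncodedLmer,
    PMSParams,
    SequenceRecord,
    decode_lmer,
    hamming_code,
)
from .enumeration import iter_candidate_codes

__all__ = [
    "BallOccurrence",
    "MotifSet",
    "scan_ball",
    "select_reference",
    "rule1",
    "rule2",
    "pairmotif_search",
    "brute_force_search",
]

logger = logging.getLogger(__name__)

_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _v in BASE_TO_BITS.items():
    _BASE_LUT[ord(_b)] = _v


@dataclass(frozen=True)
class BallOccurrence:
    """A window of a sequence lying within 2d of a query l-mer."""

    position: int
    lmer: EncodedLmer
    distance: int


@dataclass(frozen=True)
class MotifSet:
    """The answer of a planted (l, d) search: every l-mer with a window
    within distance d in every input sequence, lexicographically sorted."""

    params: PMSParams
    motifs: tuple[EncodedLmer, ...]

    def __iter__(self) -> Iterator[EncodedLmer]:
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, str):
            return item in self.strings()
        return item in self.motifs

    def strings(self) -> list[str]:
        return [decode_lmer(m) for m in self.motifs]


class _EncodedSequence:
    """Per-sequence scan cache: base indices, window codes, validity."""

    def __init__(self, record: SequenceRecord, l: int):
        if len(record) < l:
            raise ValueError(
                f"sequence {record.identifier!r} is shorter than l={l}"
            )
        self.record = record
        self.l = l
        idx = _BASE_LUT[np.frombuffer(record.residues.encode("ascii"), np.uint8)]
        self.windows = sliding_window_view(idx, l)
        self.valid = (self.windows < 4).all(axis=1)
        n_invalid = int((~self.valid).sum())
        if n_invalid:
            logger.warning(
                "sequence %r: skipping %d window(s) containing non-ACGT "
                "characters", record.identifier, n_invalid,
            )
        # packed 2-bit codes per window, rolled in one pass
        mask = (1 << (2 * l)) - 1
        codes: list[int] = []
        code = 0
        for i, v in enumerate(idx):
            code = ((code << 2) | int(v & 3)) & mask
            if i >= l - 1:
                codes.append(code)
        self.codes = codes

    def ball(self, x_idx: np.ndarray, limit: int) -> list[tuple[int, int, int]]:
        """(position, code, distance) for valid windows within ``limit``."""
        dists = (self.windows != x_idx).sum(axis=1)
        hits = np.nonzero(self.valid & (dists <= limit))[0]
        return [(int(p), self.codes[int(p)], int(dists[int(p)])) for p in hits]


def _code_to_idx(code: int, l: int) -> np.ndarray:
    return np.array(
        [(code >> (2 * (l - 1 - i))) & 3 for i in range(l)], dtype=np.uint8
    )


def scan_ball(
    x: EncodedLmer, s: SequenceRecord, params: PMSParams
) -> list[BallOccurrence]:
    """All windows of s within Hamming distance 2d of x, in position order.

    Windows containing characters outside {A, C, G, T} are skipped with a
    logged warning rather than aborting the scan.
    """
    if x.length != params.l:
        raise ValueError(f"query length {x.length} != params.l {params.l}")
    enc = _EncodedSequence(s, params.l)
    x_idx = _code_to_idx(x.code, params.l)
    return [
        BallOccurrence(
            position=p,
            lmer=EncodedLmer(code=c, length=params.l),
            distance=dist,
        )
        for p, c, dist in enc.ball(x_idx, 2 * params.d)
    ]


def select_reference(
    x: EncodedLmer,
    sequences: Sequence[SequenceRecord],
    params: PMSParams,
    counts: CandidateCountTable | None = None,
) -> int:
    """Index (into ``sequences``) of the reference for x: the sequence
    among positions 1..t-1 minimizing the summed candidate volume
    sum over x' in C(x, s_i) of |M_d(x, x')|; ties go to the lowest index.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    if counts is None:
        counts = CandidateCountTable(params)
    x_idx = _code_to_idx(x.code, params.l)
    best_i, best_sum = 1, None
    for i in range(1, len(sequences)):
        enc = _EncodedSequence(sequences[i], params.l)
        total = sum(counts[dist] for _, _, dist in enc.ball(x_idx, 2 * params.d))
        if best_sum is None or total < best_sum:
            best_i, best_sum = i, total
    return best_i


@lru_cache(maxsize=None)
def _low_mask(l: int) -> int:
    m = 0
    for _ in range(l):
        m = (m << 2) | 1
    return m


def _rule2_keep_code(
    z: int, x: int, xp: int, relation: PairRelation, params: PMSParams
) -> bool:
    l, d = params.l, params.d
    low = _low_mask(l)
    pair = x ^ xp
    pair = (pair | (pair >> 1)) & low
    zx = z ^ x
    zx = (zx | (zx >> 1)) & low
    zxp = z ^ xp
    zxp = (zxp | (zxp >> 1)) & low
    p10 = (~pair & zx & low).bit_count()
    p00 = (pair & zx & zxp).bit_count()
    for alpha, beta in relation.tuples:
        if abs(p10 - alpha) + abs(p00 - beta) <= d:
            return True
    return False


def rule1(
    z: EncodedLmer, x: EncodedLmer, x_prime: EncodedLmer, params: PMSParams
) -> bool:
    """Keep z unless it is beyond 2d from either member of the pair.

    A discarded z cannot be within d of any candidate in M_d(x, x'):
    such a candidate y satisfies d_H(z, x) <= d_H(z, y) + d_H(y, x) <= 2d.
    Returns True to keep, False to discard.
    """
    twod = 2 * params.d
    return (
        hamming_code(z.code, x.code) <= twod
        and hamming_code(z.code, x_prime.code) <= twod
    )


def rule2(
    z: EncodedLmer,
    x: EncodedLmer,
    x_prime: EncodedLmer,
    relation: PairRelation,
    params: PMSParams,
) -> bool:
    """Keep z only if some signature (alpha, beta) of the pair's mapping
    relation satisfies |p10(x,x',z) - alpha| + |p00(x,x',z) - beta| <= d.

    Catches windows that Rule 1 misses: a z equidistant from x and x'
    can still be incompatible with every admissible candidate signature.
    Returns True to keep, False to discard.
    """
    return _rule2_keep_code(z.code, x.code, x_prime.code, relation, params)


def pairmotif_search(
    sequences: Sequence[SequenceRecord], params: PMSParams
) -> MotifSet:
    """Find every (l, d) motif of the input sequences, exactly.

    Deterministic for fixed input; the result is invariant under
    reordering of sequences 2..t (reference choices may differ, the
    motif set cannot).  Candidates already accepted or refuted for an
    earlier pair are skipped: whether an l-mer is a motif is a pure
    predicate of the word and the sequences.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    l, d = params.l, params.d
    twod = 2 * d
    enc = [_EncodedSequence(s, l) for s in sequences]
    counts = CandidateCountTable(params)
    relations = {h: mapping_relation(params, h) for h in range(min(twod, l) + 1)}

    accepted: set[int] = set()
    rejected: set[int] = set()
    seen_x: set[int] = set()

    first = enc[0]
    for pos in range(len(first.codes)):
        if not first.valid[pos]:
            continue
        x_code = first.codes[pos]
        if x_code in seen_x:  # identical windows of s_1 share one outcome
            continue
        seen_x.add(x_code)
        x_idx = _code_to_idx(x_code, l)

        balls = []
        for e in enc[1:]:
            occ = e.ball(x_idx, twod)
            if not occ:
                balls = None  # some sequence has no window near x
                break
            balls.append(occ)
        if balls is None:
            continue

        # reference = smallest summed candidate volume, ties to low index
        sums = [sum(counts[dist] for _, _, dist in occ) for occ in balls]
        r = min(range(len(balls)), key=lambda i: (sums[i], i))
        others = [balls[i] for i in range(len(balls)) if i != r]

        seen_xp: set[int] = set()
        for _, xp_code, h in balls[r]:
            if xp_code in seen_xp:
                continue
            seen_xp.add(xp_code)
            relation = relations[h]

            survivor_lists = []
            dead = False
            for occ in others:
                surv = [
                    z
                    for _, z, _ in occ
                    if hamming_code(z, xp_code) <= twod  # Rule 1 (z vs x
                    # already <= 2d by ball construction)
                    and _rule2_keep_code(z, x_code, xp_code, relation, params)
                ]
                if not surv:
                    dead = True
                    break
                survivor_lists.append(surv)
            if dead:
                # no candidate of this pair can be verified; the pair is
                # abandoned without recording rejections (filtering only
                # proves absence for words inside M_d(x, x'))
                continue

            for y in iter_candidate_codes(x_code, xp_code, params):
                if y in accepted or y in rejected:
                    continue
                ok = True
                for surv in survivor_lists:
                    for z in surv:
                        if hamming_code(y, z) <= d:
                            break
                    else:
                        ok = False
                        break
                if ok:
                    accepted.add(y)
                else:
                    rejected.add(y)

    motifs = tuple(
        EncodedLmer(code=c, length=l) for c in sorted(accepted)
    )
    return MotifSet(params=params, motifs=motifs)


_BRUTE_FORCE_MAX_L = 12
_CHUNK_CELL_BUDGET = 40_000_000  # pattern x window x position bools per chunk


def brute_force_search(
    sequences: Sequence[SequenceRecord], params: PMSParams
) -> MotifSet:
    """Definitional (l, d) motif search by scanning all 4^l patterns.

    Exponential in l (guarded at l <= 12); used as the independent
    correctness oracle for :func:`pairmotif_search`.
    """
    l, d = params.l, params.d
    if l > _BRUTE_FORCE_MAX_L:
        raise ValueError(
            f"brute force limited to l <= {_BRUTE_FORCE_MAX_L}, got l={l}"
        )
    if len(sequences) < 1:
        raise ValueError("need at least one sequence")
    enc = [_EncodedSequence(s, l) for s in sequences]
    wins = [e.windows[e.valid] for e in enc]
    if any(w.shape[0] == 0 for w in wins):
        return MotifSet(params=params, motifs=())

    max_windows = max(w.shape[0] for w in wins)
    chunk = max(1, min(4**l, _CHUNK_CELL_BUDGET // (max_windows * l)))
    place = 4 ** np.arange(l - 1, -1, -1, dtype=np.int64)

    survivors: list[int] = []
    for start in range(0, 4**l, chunk):
        codes = np.arange(start, min(start + chunk, 4**l), dtype=np.int64)
        pat = (codes[:, None] // place[None, :]) % 4  # base-4 digits
        keep = np.ones(len(codes), dtype=bool)
        for w in wins:
            dmin = (
                (pat[:, None, :] != w[None, :, :]).sum(axis=2).min(axis=1)
            )
            keep &= dmin <= d
            if not keep.any():
                break
        survivors.extend(int(c) for c in codes[keep])

    motifs = tuple(EncodedLmer(code=c, length=l) for c in sorted(survivors))
    return MotifSet(params=params, motifs=motifs)
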