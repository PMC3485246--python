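"""Motif ranking objectives and nucleotide-level evaluation.

An exact (l, d) search reports *every* motif; to predict a single
binding site the reported motifs are ranked by an objective function
over their best per-sequence occurrences:

* consensus score — sum over columns of the most frequent base's count
  (maximal, t*l, iff all occurrences are identical);
* relative entropy — Kullback-Leibler divergence (in bits) of the
  column base frequencies from a background distribution, summed over
  columns, with a pseudocount to keep it finite.

Predictions are assessed at nucleotide level with the correlation
coefficient

    nCC = (nTP*nTN - nFN*nFP)
          / sqrt((nTP+nFN)(nTN+nFP)(nTP+nFP)(nTN+nFN)),

where the confusion counts classify each sequence position by whether
the predicted and the true site cover it.  nCC ranges from -1 (perfect
anticorrelation) to +1 (perfect prediction) and is undefined when a
denominator factor vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EncodedLmer, PMSParams, SequenceRecord, decode_lmer
from .search import _EncodedSequence, _code_to_idx

__all__ = [
    "InstanceAlignment",
    "ConfusionCounts",
    "UndefinedMetricError",
    "extract_instances",
    "consensus_score",
    "relative_entropy",
    "dataset_base_frequencies",
    "ncc",
    "confusion_from_positions",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator vanished; the value does not exist."""


@dataclass(frozen=True)
class InstanceAlignment:
    """A motif with its best occurrence in every sequence.

    ``instances`` holds one (position, word, distance) triple per
    sequence; ``counts`` is the 4 x l column base-count matrix of the
    aligned occurrence words (rows in A, C, G, T order; every column
    sums to the number of sequences).
    """

    motif: EncodedLmer
    instances: tuple[tuple[int, str, int], ...]
    counts: np.ndarray

    @property
    def n_sequences(self) -> int:
        return len(self.instances)


def extract_instances(
    motif: EncodedLmer,
    sequences: Sequence[SequenceRecord],
    params: PMSParams,
) -> InstanceAlignment:
    """Locate the minimum-distance window of each sequence (ties go to
    the leftmost) and tally the column base counts.

    Raises ValueError if some sequence has no window within d — the
    motif then violates the (l, d) motif contract for these sequences.
    """
    l, d = params.l, params.d
    if motif.length != l:
        raise ValueError(f"motif length {motif.length} != params.l {l}")
    m_idx = _code_to_idx(motif.code, l)
    instances = []
    counts = np.zeros((4, l), dtype=np.int64)
    for s in sequences:
        enc = _EncodedSequence(s, l)
        dists = (enc.windows != m_idx).sum(axis=1)
        dists = np.where(enc.valid, dists, l + 1)
        pos = int(np.argmin(dists))  # argmin is leftmost on ties
        dist = int(dists[pos])
        if dist > d:
            raise ValueError(
                f"sequence {s.identifier!r} has no window within d={d} of "
                f"motif {decode_lmer(motif)} (best distance {dist})"
            )
        word_idx = enc.windows[pos]
        instances.append((pos, s.residues[pos : pos + l], dist))
        counts[word_idx, np.arange(l)] += 1
    return InstanceAlignment(
        motif=motif, instances=tuple(instances), counts=counts
    )


def consensus_score(alignment: InstanceAlignment) -> int:
    """Sum over columns of the most frequent base's count."""
    return int(alignment.counts.max(axis=0).sum())


def dataset_base_frequencies(
    sequences: Sequence[SequenceRecord],
) -> np.ndarray:
    """Overall A/C/G/T frequencies of a sequence set (background model)."""
    totals = np.zeros(4, dtype=np.int64)
    for s in sequences:
        for i, b in enumerate("ACGT"):
            totals[i] += s.residues.count(b)
    if totals.sum() == 0:
        raise ValueError("sequences contain no ACGT characters")
    return totals / totals.sum()


def relative_entropy(
    alignment: InstanceAlignment,
    background: np.ndarray | None = None,
    pseudocount: float = 0.25,
) -> float:
    """Column-summed KL divergence (bits) of the occurrence profile from
    a background base distribution.

    Column frequencies are formed from counts with ``pseudocount`` added
    per base; ``background`` defaults to uniform and must be strictly
    positive.  Nonnegative whenever the background equals the column
    marginal; always finite for a positive pseudocount.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 strictly positive frequencies")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    t = alignment.n_sequences
    freqs = (alignment.counts + pseudocount) / (t + 4 * pseudocount)
    total = 0.0
    for col in range(freqs.shape[1]):
        for b in range(4):
            f = freqs[b, col]
            if f > 0:
                total += f * math.log2(f / background[b])
    return total


@dataclass(frozen=True)
class ConfusionCounts:
    """Nucleotide-level confusion counts between predicted and true sites."""

    nTP: int
    nTN: int
    nFN: int
    nFP: int

    @property
    def total(self) -> int:
        return self.nTP + self.nTN + self.nFN + self.nFP


def ncc(counts: ConfusionCounts) -> float:
    """Nucleotide-level correlation coefficient in [-1, 1].

    Raises :class:`UndefinedMetricError` when any denominator factor is
    zero (e.g. no true site or no predicted site) rather than reporting
    a silent 0.
    """
    tp, tn, fn, fp = counts.nTP, counts.nTN, counts.nFN, counts.nFP
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom == 0:
        raise UndefinedMetricError(
            f"nCC undefined: zero factor in denominator for {counts}"
        )
    return (tp * tn - fn * fp) / math.sqrt(denom)


def confusion_from_positions(
    predicted: Sequence[int],
    truth: Sequence[int],
    n: int,
    params: PMSParams,
) -> ConfusionCounts:
    """Confusion counts from per-sequence predicted and true site starts.

    Each site is the half-open window [p, p + l); each of the n
    positions of every sequence is TP if covered by both windows, FP if
    only predicted, FN if only true, TN if neither.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must cover the same sequences")
    l = params.l
    tp = tn = fn = fp = 0
    for p, q in zip(predicted, truth):
        for name, start in (("predicted", p), ("truth", q)):
            if not (0 <= start <= n - l):
                raise ValueError(
                    f"{name} window start {start} outside [0, {n - l}]"
                )
        overlap = max(0, min(p + l, q + l) - max(p, q))
        tp += overlap
        fp += l - overlap
        fn += l - overlap
        tn += n - 2 * l + overlap
    return ConfusionCounts(nTP=tp, nTN=tn, nFN=fn, nFP=fp)
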