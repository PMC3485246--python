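"""Core domain types: l-mer encoding, Hamming distance, position partitions.

DNA words of fixed length *l* are packed two bits per base into a plain
Python integer (``A=00, C=01, G=10, T=11``), with the first character of
the word in the most significant bits.  This makes the numeric order of
codes coincide with lexicographic order of the words, and lets a sliding
window over a sequence update its code with one shift and one OR.

Hamming distances between encoded words are computed by XOR-ing the two
codes and counting the non-zero 2-bit fields of the result with a
256-entry byte table (``ceil(l/4)`` lookups per distance).  The table
method is exactly equivalent to position-by-position comparison and is
verified against it in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BASES",
    "BASE_TO_BITS",
    "PMSParams",
    "SequenceRecord",
    "EncodedLmer",
    "PartitionCounts",
    "encode_lmer",
    "decode_lmer",
    "hamming",
    "hamming_naive",
    "partition_counts",
]

BASES = "ACGT"
BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}

#: byte -> number of 2-bit fields that are not 00 (used on XOR output)
_NONZERO_PAIRS_IN_BYTE = tuple(
    sum(1 for shift in (0, 2, 4, 6) if (b >> shift) & 3) for b in range(256)
)


class InvalidSequenceError(ValueError):
    """A DNA string contains a character outside {A, C, G, T}."""


@dataclass(frozen=True)
class PMSParams:
    """Parameters of a planted (l, d) motif search instance.

    l : motif length in bases.
    d : maximum number of mutations allowed per motif occurrence.

    Requires 0 <= d < l.  Note that 2d < l is *not* required: instances
    such as (5, 3) are legal, although pairs of occurrences at distance
    greater than 2d never arise and are pruned by the search.
    """

    l: int
    d: int

    def __post_init__(self) -> None:
        if not (0 <= self.d < self.l):
            raise ValueError(
                f"require 0 <= d < l, got (l={self.l}, d={self.d})"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence restricted to the 4-letter alphabet."""

    identifier: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class EncodedLmer:
    """An l-length DNA word packed 2 bits per base.

    ``code`` holds the packed integer (``code < 4**length``); the first
    base occupies the highest-order bit pair.
    """

    code: int
    length: int

    def __post_init__(self) -> None:
        if self.code < 0 or self.code >> (2 * self.length):
            raise ValueError(
                f"code {self.code} out of range for length {self.length}"
            )

    def __str__(self) -> str:
        return decode_lmer(self)


def encode_lmer(word: str) -> EncodedLmer:
    """Pack a DNA word into its 2-bit integer code.

    Raises :class:`InvalidSequenceError` naming the first offending
    position if the word contains a character outside {A, C, G, T}.
    """
    code = 0
    for i, ch in enumerate(word):
        try:
            code = (code << 2) | BASE_TO_BITS[ch]
        except KeyError:
            raise InvalidSequenceError(
                f"non-ACGT character {ch!r} at position {i}"
            ) from None
    return EncodedLmer(code=code, length=len(word))


def decode_lmer(lmer: EncodedLmer) -> str:
    """Invert :func:`encode_lmer`."""
    code, l = lmer.code, lmer.length
    return "".join(BASES[(code >> (2 * (l - 1 - i))) & 3] for i in range(l))


def hamming_code(a: int, b: int) -> int:
    """Hamming distance between two packed codes of the same length.

    XOR the codes, then count non-00 bit pairs one byte at a time via the
    precomputed 256-entry table.
    """
    x = a ^ b
    dist = 0
    while x:
        dist += _NONZERO_PAIRS_IN_BYTE[x & 0xFF]
        x >>= 8
    return dist


def hamming(x: EncodedLmer, y: EncodedLmer) -> int:
    """Table-accelerated Hamming distance between two encoded l-mers."""
    if x.length != y.length:
        raise ValueError(f"length mismatch: {x.length} != {y.length}")
    return hamming_code(x.code, y.code)


def hamming_naive(x: str, y: str) -> int:
    """Position-by-position Hamming distance on raw strings (reference)."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} != {len(y)}")
    return sum(1 for a, b in zip(x, y) if a != b)


@dataclass(frozen=True)
class PartitionCounts:
    """Sizes of the four position classes in the alignment of (x, x', z).

    A position i is class ``ab`` where a = 1 iff x[i] = x'[i] and
    b = 1 iff z[i] matches x[i] or x'[i].  Consequently
    p11 + p10 = l - d_H(x, x') and p01 + p00 = d_H(x, x').
    """

    p11: int
    p10: int
    p01: int
    p00: int

    @property
    def total(self) -> int:
        return self.p11 + self.p10 + self.p01 + self.p00


# Mask selecting the low bit of every 2-bit field for a word of length l.
def _low_bits_mask(l: int) -> int:
    m = 0
    for _ in range(l):
        m = (m << 2) | 1
    return m


def _mismatch_flags(a: int, b: int, l: int) -> int:
    """One flag bit (in the low position of each 2-bit field) per
    position where the two codes disagree."""
    x = a ^ b
    return (x | (x >> 1)) & _low_bits_mask(l)


def partition_counts(
    x: EncodedLmer, x_prime: EncodedLmer, z: EncodedLmer
) -> PartitionCounts:
    """Classify alignment positions of (x, x', z) into P11/P10/P01/P00."""
    if not (x.length == x_prime.length == z.length):
        raise ValueError("length mismatch among x, x', z")
    l = x.length
    pair_diff = _mismatch_flags(x.code, x_prime.code, l)  # x[i] != x'[i]
    zx_diff = _mismatch_flags(z.code, x.code, l)
    zxp_diff = _mismatch_flags(z.code, x_prime.code, l)

    p10 = (~pair_diff & zx_diff & _low_bits_mask(l)).bit_count()
    p11 = (l - hamming(x, x_prime)) - p10
    p00 = (pair_diff & zx_diff & zxp_diff).bit_count()
    p01 = hamming(x, x_prime) - p00
    return PartitionCounts(p11=p11, p10=p10, p01=p01, p00=p00)
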