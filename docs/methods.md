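# Methods

## Model and scope

The package solves planted (l, d) motif search exactly: given sequences
s_1..s_t over {A, C, G, T} and 0 ≤ d < l, report every l-mer m such that
each s_i has a window within Hamming distance d of m.  Reported sets are
complete and sound — the central invariant, tested by comparing against
a definitional brute-force scan of all 4^l patterns on randomized small
instances.  Matching is on the forward strand only and literal: no
reverse complements, no IUPAC ambiguity codes.  Windows containing
characters outside the 4-letter alphabet (e.g. N) cannot be motif
occurrences or evidence for one; they are skipped with a logged warning
rather than aborting, so masked genomic sequence remains usable.

## Encoding and distances

Words are packed 2 bits per base, A=00, C=01, G=10, T=11, first base in
the most significant bits.  Any bijection would do; this one is fixed so
that codes are reproducible across runs and numeric order equals
lexicographic order (reports sort by code).  Distances XOR the two codes
and count non-zero 2-bit fields with a 256-entry byte table (⌈l/4⌉
lookups).  High-bit padding for l not a multiple of 4 XORs to zero and
contributes nothing.  The table method is verified against direct
positional comparison for every l in 4..32.

## Pair combinatorics

For a pair at distance h, a member y of the ball intersection
M_d(x, x′) is classified per position: P11/P10 where x and x′ agree and
y matches/differs, P01/P00 where they disagree and y matches one/neither.
With α = |P10|, β = |P00| and k = the number of disagreeing positions
where y takes x's base, d_H(y, x) = α + h − k and d_H(y, x′) = α + β + k,
so feasibility of (α, β) is exactly non-emptiness of

    max(0, α + h − d) ≤ k ≤ min(h − β, d − α − β).

The mapping relation enumerates these signatures; the candidate count

    |M_d| = Σ_{(α,β)} C(l−h, α)·3^α · C(h, β)·2^β · Σ_k C(h−β, k)

uses exact integer arithmetic throughout (counts overflow 64 bits for
large l).  Counts are cached per h = 0..2d before a search begins.

For the (15, 4) instance the published reference table agrees with this
closed form at h ∈ {8, 7, 6, 5, 2, 1}.  At h ∈ {4, 3, 0} the published
values (6600, 13504, 100636) disagree with exhaustive enumeration of the
set definition itself (our formula gives 6856, 13060, 123841; the h = 0
entry must equal the radius-d ball size Σ_{i≤4} C(15, i)·3^i = 123841).
The implementation trusts the definition, which the 4^l oracle confirms
at every reduced scale tested; the three divergent cells are treated as
typographical.

The weakness index p_k — the probability that two uniform random l-mers
lie within distance k — is the Binomial(l, 3/4) CDF at k, evaluated in
exact rational arithmetic and cross-checked against an independent CDF
implementation.  The published 3-decimal column appears truncated rather
than rounded (0.53458 printed as 0.534), and its (27, 9) entry (0.213)
is one unit in the last digit below the exact 0.21405; tests assert the
exact values and printed agreement at the 2·10⁻³ level.

## Candidate traversal

Candidates are generated lazily, starting from y = x′: choose α agreeing
positions and set each to one of the 3 non-x bases; choose β disagreeing
positions and set each to one of the 2 bases matching neither word;
choose k further disagreeing positions and reset each to x's base.  Each
(signature, positions, characters, k) tuple produces a distinct word and
the signature subsets are disjoint, so every candidate is emitted exactly
once — asserted against the brute-force set on random pairs at every
feasible h.  Emission order (signatures lexicographic; then position
subsets, character substitutions, and k in canonical ascending order) is
a package choice fixed purely for reproducibility; only the emitted set
is contractual.  h = 0 flows through the same code path (β and the
signature slack force k = 0) rather than a special case.

## Search engine choices

- Identical l-mer strings at multiple positions of s_1 (or of the
  reference) are processed once: the answer depends only on strings.
- If some C(x, s_i) is empty, x is skipped immediately — a motif with an
  occurrence at x would put its s_i occurrence within 2d of x.
- Rule 1 is applied before Rule 2 (cheaper); both run on every window
  already within 2d of x.
- Verification checks only sequences other than s_1 and the reference
  (x and x′ witness those); the test suite re-validates accepted motifs
  against *all* sequences rather than assuming this.
- Whether a candidate is a motif is a pure predicate of (word,
  sequences), so per-run memos of accepted and refuted candidate codes
  skip re-verification across pairs.  A refutation is only recorded when
  the candidate was actually verified; pairs abandoned because some
  filtered window list came up empty record nothing.
- Output is deduplicated and sorted lexicographically; coordinates are
  0-based, half-open [p, p + l).
- Reference-sequence ties break to the lowest index.  The motif set is
  invariant under reordering of s_2..s_t (tested); internal reference
  choices need not be.

The brute-force oracle enumerates all 4^l patterns (guarded at l ≤ 12)
with vectorized distance minima, chunked to bound memory.  It shares no
code with the pair-driven path beyond the sequence container.

## Simulator

The generator reproduces the standard planted-instance protocol:
background bases i.i.d. uniform; one occurrence of a common random motif
written over the background of each sequence at a uniform position.
Defaults t = 20, n = 600 match the benchmark geometry.  Because the
planted-motif literature is split between "exactly d" and "up to d"
mutations, both are supported; the default is `exactly_d`, the harder
fixed-mutation benchmark model.  Mutated positions are a uniform subset
of the l positions and each mutated base is uniformly one of the three
alternatives.  A single seeded generator is consumed in a fixed order
(motif; then per sequence: background, position, mutation count,
positions, bases), so a seed fully determines the dataset, its FASTA
serialization, and the ground-truth manifest.

What the simulator does *not* emulate: biased base composition,
correlated columns within sites, multiple or missing occurrences per
sequence, decoy motifs.  Tests passing on this model certify the
combinatorial machinery, not performance on real promoters; on real data
the (l, d) motif set can be large and ranking quality then dominates.

## Ranking and evaluation

A motif's occurrence set is its minimum-distance window per sequence,
ties to the leftmost.  Consensus score sums the per-column maximum base
count (maximal, t·l, iff all occurrences are identical).  Relative
entropy sums, over columns, the KL divergence (base-2 logarithm, bits)
of column frequencies from a background distribution; frequencies use a
pseudocount of 0.25 per base per column to stay finite, and the default
background is the whole-dataset base composition (uniform available by
flag).  nCC classifies every sequence position by predicted/true site
coverage and is the Matthews-style correlation of those counts; a zero
denominator factor raises an explicit "undefined" error instead of
returning 0.  The evaluation assumes exactly one true site per sequence,
as recorded in the simulator manifest; published site annotations that
skip sequences would need adaptation.

## Problem sizes used in the checks

Oracle-equivalence sweeps use l ≤ 8, d ≤ 2, t ≤ 5, n ≤ 50 (where 4^l
enumeration is exact and fast); planted-recovery checks use (11, 2) at
t = 20, n = 100 and (15, 4) at t = 20, n = 200, both of which also pass
at the full n = 600 benchmark geometry (about 5 s for (15, 4) in this
implementation).  Scaling beyond that — the weak instances (19, 7) or
(27, 9) at full size — is a matter of hours, as expected for an exact
exponential-worst-case method in pure Python, and is not exercised by
the test suite.

## Known limitations

- Pure-Python hot loop: orders of magnitude slower than a C
  implementation on weak instances; the algorithmic profile (stable in
  n, sharp dependence on p_2d) is unchanged.
- No branch-and-bound inside the candidate traversal, and no parallel
  processing of the independent s_1 l-mers.
- Ranking objectives are position-independent; interdependent binding
  site positions are not modelled.
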