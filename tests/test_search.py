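"""Pair-driven exact search: scanning, reference choice, filtering rules,
full-search correctness against the definitional brute-force oracle."""

import random

import pytest

from pairmotif.combinatorics import CandidateCountTable, mapping_relation
from pairmotif.core import (
    PMSParams,
    SequenceRecord,
    encode_lmer,
    hamming,
    hamming_naive,
)
from pairmotif.enumeration import enumerate_candidates
from pairmotif.search import (
    brute_force_search,
    pairmotif_search,
    rule1,
    rule2,
    scan_ball,
    select_reference,
)

from .conftest import random_records, random_word, word_at_distance


class TestScanBall:
    def test_exact_occurrence_reported_at_distance_zero(self):
        params = PMSParams(5, 1)
        s = SequenceRecord("s", "TTTTTACGTATTTT")
        occ = scan_ball(encode_lmer("ACGTA"), s, params)
        hits = {o.position: o.distance for o in occ}
        assert hits[5] == 0

    def test_no_window_within_2d_gives_empty(self):
        params = PMSParams(4, 0)
        s = SequenceRecord("s", "CCCCCCCC")
        assert scan_ball(encode_lmer("AAAA"), s, params) == []

    def test_matches_naive_window_filter(self, rng):
        params = PMSParams(8, 2)
        x = random_word(rng, 8)
        seq = random_word(rng, 60)
        occ = scan_ball(encode_lmer(x), SequenceRecord("s", seq), params)
        naive = [
            (p, hamming_naive(x, seq[p : p + 8]))
            for p in range(len(seq) - 7)
            if hamming_naive(x, seq[p : p + 8]) <= 4
        ]
        assert [(o.position, o.distance) for o in occ] == naive
        positions = [o.position for o in occ]
        assert positions == sorted(positions)

    def test_non_acgt_windows_skipped(self):
        params = PMSParams(4, 1)
        s = SequenceRecord("s", "ACGTNACGT")
        occ = scan_ball(encode_lmer("ACGT"), s, params)
        # windows 1..4 all contain the N and must be absent
        assert {o.position for o in occ} == {0, 5}

    def test_sequence_shorter_than_l_rejected(self):
        params = PMSParams(6, 1)
        with pytest.raises(ValueError, match="shorter"):
            scan_ball(encode_lmer("ACGTAC"), SequenceRecord("s", "ACG"), params)


class TestSelectReference:
    def test_two_sequences_only_one_choice(self, rng):
        params = PMSParams(6, 1)
        seqs = random_records(rng, 2, 30)
        assert select_reference(encode_lmer(random_word(rng, 6)), seqs, params) == 1

    def test_prefers_distant_windows_over_exact_copy(self):
        # an exact copy of x carries the huge h=0 candidate volume, so the
        # sequence whose windows all sit at 2d wins
        params = PMSParams(5, 1)
        x = "ACGTA"
        near = SequenceRecord("near", "ACGTA" + "ACGTA")
        far = SequenceRecord("far", "AGTTA" + "CCCCC")  # distance 2 = 2d
        seqs = [SequenceRecord("first", "G" * 10), near, far]
        assert select_reference(encode_lmer(x), seqs, params) == 2

    def test_tie_broken_by_lowest_index(self):
        params = PMSParams(4, 1)
        x = encode_lmer("AAAA")
        twin = "AATTTTAA"  # same window multiset either way
        seqs = [
            SequenceRecord("first", "CCCCCCCC"),
            SequenceRecord("a", twin),
            SequenceRecord("b", twin),
        ]
        assert select_reference(x, seqs, params) == 1

    def test_agrees_with_explicit_count_sum(self, rng):
        params = PMSParams(6, 2)
        counts = CandidateCountTable(params)
        x = encode_lmer(random_word(rng, 6))
        seqs = random_records(rng, 5, 40)
        totals = []
        for s in seqs[1:]:
            occ = scan_ball(x, s, params)
            totals.append(sum(counts[o.distance] for o in occ))
        expected = 1 + min(range(len(totals)), key=lambda i: (totals[i], i))
        assert select_reference(x, seqs, params, counts) == expected


class TestFilteringRules:
    params = PMSParams(15, 4)
    x = encode_lmer("AAAAAAAGGGGGGGG")
    xp = encode_lmer("AAAAAAACCCCCCCC")

    def test_rule1_worked_example(self):
        z = encode_lmer("TTTTAAAGGGGGGGG")  # distance 12 > 2d from x'
        assert hamming(z, self.xp) == 12
        assert rule1(z, self.x, self.xp, self.params) is False
        assert rule1(self.x, self.x, self.xp, self.params) is True

    def test_rule2_worked_example(self):
        rel = mapping_relation(self.params, 8)
        z_caught = encode_lmer("AAAAAAATTTTTTTT")  # statistic 0+8 = 8 > d
        z_kept = encode_lmer("TTTTAAAGGGGGGGG")  # statistic 4+0 = 4 <= d
        assert rule2(z_caught, self.x, self.xp, rel, self.params) is False
        assert rule2(z_kept, self.x, self.xp, rel, self.params) is True

    def test_rule2_keeps_pair_member(self):
        rel = mapping_relation(self.params, 8)
        assert rule2(self.xp, self.x, self.xp, rel, self.params) is True

    def test_discarded_lmers_are_never_near_any_candidate(self, rng):
        # soundness of both rules: a filtered-out z must lie beyond d of
        # every member of M_d(x, x'), checked by exhaustive enumeration
        params = PMSParams(7, 2)
        checked = 0
        for _ in range(300):
            x_w = random_word(rng, 7)
            xp_w = word_at_distance(rng, x_w, rng.randint(0, 4))
            z_w = random_word(rng, 7)
            x, xp, z = (encode_lmer(w) for w in (x_w, xp_w, z_w))
            rel = mapping_relation(params, hamming(x, xp))
            if rule1(z, x, xp, params) and rule2(z, x, xp, rel, params):
                continue
            checked += 1
            for y in enumerate_candidates(x, xp, params):
                assert hamming(z, y) > params.d, (x_w, xp_w, z_w)
        assert checked > 50  # the sample actually exercised the rules


def _search_both_ways(seqs, params):
    got = pairmotif_search(seqs, params)
    want = brute_force_search(seqs, params)
    assert list(got.motifs) == list(want.motifs)
    return got


class TestPairMotifSearch:
    def test_d_zero_finds_exact_common_lmers(self):
        params = PMSParams(4, 0)
        seqs = [
            SequenceRecord("a", "ACGTACCA"),
            SequenceRecord("b", "TTACGTAC"),
            SequenceRecord("c", "CGACGTTA"),
        ]
        got = pairmotif_search(seqs, params)
        assert got.strings() == ["ACGT"]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(12):
            l = rng.randint(4, 8)
            d = rng.randint(0, min(2, l - 1))
            seqs = random_records(rng, rng.randint(2, 5), rng.randint(l + 2, 50))
            _search_both_ways(seqs, PMSParams(l, d))

    def test_accepted_motifs_hold_in_every_sequence(self, rng):
        # re-validate the verification shortcut (sequences 1 and r are
        # witnessed by x and x') directly against all sequences
        params = PMSParams(5, 2)
        seqs = random_records(rng, 4, 25)
        got = pairmotif_search(seqs, params)
        for m in got.motifs:
            for s in seqs:
                assert min(
                    hamming_naive(str(m), s.residues[p : p + 5])
                    for p in range(len(s) - 4)
                ) <= 2

    def test_invariant_under_reordering_tail_sequences(self, rng):
        params = PMSParams(5, 1)
        seqs = random_records(rng, 5, 30)
        base = pairmotif_search(seqs, params)
        shuffled = [seqs[0]] + random.Random(5).sample(seqs[1:], len(seqs) - 1)
        assert pairmotif_search(shuffled, params).motifs == base.motifs

    def test_planted_motif_recovered(self):
        from pairmotif.simulate import generate_planted

        params = PMSParams(8, 1)
        ds = generate_planted(params, t=10, n=60, seed=42)
        got = _search_both_ways(list(ds.sequences), params)
        assert ds.motif in got

    def test_two_sequence_instance(self, rng):
        params = PMSParams(5, 1)
        seqs = random_records(rng, 2, 30)
        _search_both_ways(seqs, params)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairmotif_search(
                [SequenceRecord("a", "ACGTACGT")], PMSParams(4, 1)
            )


class TestBruteForce:
    def test_single_exact_sequence(self):
        got = brute_force_search(
            [SequenceRecord("a", "ACGT")], PMSParams(4, 0)
        )
        assert got.strings() == ["ACGT"]

    def test_loose_radius_never_empty(self, rng):
        params = PMSParams(4, 3)
        seqs = random_records(rng, 2, 12)
        assert len(brute_force_search(seqs, params)) > 0

    def test_identical_sequences_agree_with_pairmotif(self, rng):
        params = PMSParams(5, 1)
        s = random_word(rng, 20)
        seqs = [SequenceRecord(f"s{i}", s) for i in range(3)]
        got = _search_both_ways(seqs, params)
        # every window of the shared sequence is itself a motif
        for p in range(len(s) - 4):
            assert s[p : p + 5] in got

    def test_large_l_guarded(self):
        with pytest.raises(ValueError):
            brute_force_search(
                [SequenceRecord("a", "A" * 20)], PMSParams(13, 1)
            )
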