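"""Hairpin candidate screening, locus strings, conservation and pairing."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soymir.fold import fold_hairpin
from soymir.mapping import MatchLocus
from soymir.novel import (
    candidate_windows,
    conservativeness,
    five_prime_composition,
    locus_string,
    mircheck,
    pair_bidirectional,
    parse_locus_string,
)
from soymir.seqs import revcomp


def make_hairpin(mature, left_pad, right_pad, loop, mismatch_positions=()):
    """arm5(=pads+mature) + loop + revcomp(arm5) with substitutions at the
    given arm5 partner positions."""
    rng = random.Random(11)
    pad = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    arm5 = pad(left_pad) + mature + pad(right_pad)
    comp = list(revcomp(arm5))
    for i in mismatch_positions:  # i indexes arm5; partner index mirrors
        j = len(arm5) - 1 - i
        comp[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[comp[j]]
    return arm5 + loop + "".join(comp)


MATURE = "TAAGGCTCAGTAGGCATCGATG"  # 22 nt


class TestMircheck:
    def test_perfect_stem_hairpin_passes(self):
        pre = make_hairpin(MATURE, 6, 30, "AACCAAGGAA")
        fold = fold_hairpin(pre)
        pos = pre.find(MATURE) + 1
        ok, reason = mircheck(fold, pos, pos + len(MATURE) - 1)
        assert ok, reason

    def test_mature_straddling_loop_fails(self):
        pre = make_hairpin(MATURE, 6, 30, "AACCAAGGAA")
        fold = fold_hairpin(pre)
        # place the "mature" across the loop centre
        centre = 6 + len(MATURE) + 30 + 5
        ok, reason = mircheck(fold, centre - 10, centre + 11)
        assert not ok
        assert reason in {"mature-in-terminal-loop", "mature-not-on-single-arm"}

    def test_five_unpaired_mature_bases_fail_default_threshold(self):
        arm_pos = [8, 11, 14, 17, 20]  # five partner mismatches inside mature
        pre = make_hairpin(MATURE, 6, 30, "AACCAAGGAA", arm_pos)
        fold = fold_hairpin(pre)
        pos = pre.find(MATURE) + 1
        ok, reason = mircheck(fold, pos, pos + len(MATURE) - 1)
        assert not ok

    def test_mature_length_gate(self):
        pre = make_hairpin(MATURE, 6, 30, "AACCAAGGAA")
        fold = fold_hairpin(pre)
        ok, reason = mircheck(fold, 7, 7 + 18)  # 19 nt
        assert not ok and reason == "mature-length"

    def test_short_hairpin_fails_span_gate(self):
        pre = make_hairpin(MATURE, 1, 2, "ACAA")  # ~54 nt hairpin
        fold = fold_hairpin(pre)
        pos = pre.find(MATURE) + 1
        ok, reason = mircheck(fold, pos, pos + len(MATURE) - 1)
        assert not ok

    def test_planted_hairpins_pass_at_exact_extent(self, small_dataset):
        for rec in small_dataset.truth.mirnas.values():
            fold = fold_hairpin(rec.precursor)
            pos = rec.precursor.find(rec.mature) + 1
            ok, reason = mircheck(fold, pos, pos + len(rec.mature) - 1)
            assert ok, (rec.mirna_id, reason)


class TestCandidateWindows:
    GENOME = {"c": "ACGT" * 300}

    def test_zero_flank_returns_read_itself(self):
        locus = MatchLocus("c", "+", 101, 122)
        windows = candidate_windows(locus, self.GENOME, flank=0)
        assert all(len(seq) == 22 for seq, _loc in windows)

    def test_truncated_at_chromosome_start(self):
        locus = MatchLocus("c", "+", 10, 31)
        windows = candidate_windows(locus, self.GENOME, flank=200)
        (seq_a, loc_a), (seq_b, loc_b) = windows
        assert loc_b.start == 1  # upstream flank truncated, no error
        assert len(seq_b) == 31

    def test_minus_strand_windows_are_reverse_complemented(self):
        genome = {"c": "A" * 50 + "TTTGGGCCCAAATTTGGGCG" + "A" * 50}
        locus = MatchLocus("c", "-", 51, 70)
        for seq, _loc in candidate_windows(locus, genome, flank=10):
            assert revcomp("TTTGGGCCCAAATTTGGGCG") in seq

    def test_window_contains_planted_precursor(self, small_dataset):
        truth = small_dataset.truth
        for rec in truth.mirnas.values():
            m_start = rec.precursor.find(rec.mature)
            if rec.locus.strand == "+":
                m_locus = MatchLocus(
                    rec.locus.chrom,
                    "+",
                    rec.locus.start + m_start,
                    rec.locus.start + m_start + len(rec.mature) - 1,
                )
            else:
                m_locus = MatchLocus(
                    rec.locus.chrom,
                    "-",
                    rec.locus.end - m_start - len(rec.mature) + 1,
                    rec.locus.end - m_start,
                )
            windows = candidate_windows(m_locus, small_dataset.genome, flank=200)
            # windows are anchored at the read: the downstream window holds
            # the precursor from the mature onward, the upstream window holds
            # it through the mature; together they cover the full hairpin
            down, up = windows[0][0], windows[1][0]
            m_end = m_start + len(rec.mature)
            assert rec.precursor[m_start:] in down, rec.mirna_id
            assert rec.precursor[:m_end] in up, rec.mirna_id


class TestLocusString:
    @pytest.mark.parametrize(
        "fields,expected",
        [
            (("Gm02", "+", 39925524, 39925657), "Gm02_+_39925524_39925657"),
            (("Gm08", "-", 4271026, 4271087), "Gm08_-_4271026_4271087"),
        ],
    )
    def test_format(self, fields, expected):
        assert locus_string(*fields) == expected

    def test_round_trip(self):
        s = "Gm13_-_14700000_14700030"
        locus = parse_locus_string(s)
        assert locus_string(locus.chrom, locus.strand, locus.start, locus.end) == s

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        chrom=st.from_regex(r"Gm[0-9]{2}", fullmatch=True),
        strand=st.sampled_from("+-"),
        start=st.integers(1, 10**8),
        length=st.integers(1, 300),
    )
    def test_round_trip_property(self, chrom, strand, start, length):
        s = locus_string(chrom, strand, start, start + length - 1)
        locus = parse_locus_string(s)
        assert (locus.chrom, locus.strand, locus.start, locus.end) == (
            chrom,
            strand,
            start,
            start + length - 1,
        )

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_locus_string("Gm02:+:5:10")


class TestPairBidirectional:
    def _cand(self, chrom, strand, start, end):
        from soymir.novel import HairpinCandidate
        from soymir.fold import FoldResult

        return HairpinCandidate(
            mature="T" * 21,
            arm="5p",
            precursor="A" * (end - start + 1),
            fold=FoldResult("A", ".", [], 0),
            locus=MatchLocus(chrom, strand, start, end),
        )

    def test_published_pair_intervals_pair_up(self):
        a = self._cand("Gm02", "+", 39925524, 39925657)
        b = self._cand("Gm02", "-", 39925526, 39925654)
        assert len(pair_bidirectional([a, b])) == 1

    def test_same_strand_overlap_is_not_a_pair(self):
        a = self._cand("Gm02", "+", 100, 220)
        b = self._cand("Gm02", "+", 102, 218)
        assert pair_bidirectional([a, b]) == []

    def test_disjoint_intervals_are_not_a_pair(self):
        a = self._cand("Gm02", "+", 100, 220)
        b = self._cand("Gm02", "-", 500, 620)
        assert pair_bidirectional([a, b]) == []


class TestConservativeness:
    KNOWN = {"gma-MIR1516a": "ACGTTGCAGGTCCAAGGTTACGATCGGATCGGCTAGCTAAGGCTCAGT" * 2}

    def test_identical_precursor_found(self):
        name = conservativeness(self.KNOWN["gma-MIR1516a"], self.KNOWN)
        assert name == "gma-MIR1516a"

    def test_random_sequence_not_conserved(self):
        rng = random.Random(2)
        seq = "".join(rng.choice("ACGT") for _ in range(100))
        assert conservativeness(seq, self.KNOWN) is None

    def test_85_percent_identical_copy_found(self):
        rng = random.Random(3)
        ref = self.KNOWN["gma-MIR1516a"]
        mutated = list(ref)
        for i in rng.sample(range(len(ref)), int(0.15 * len(ref))):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        assert conservativeness("".join(mutated), self.KNOWN) == "gma-MIR1516a"


class TestFivePrimeComposition:
    # the fourteen published novel mature candidates
    PUBLISHED = [
        "AUAUAUUUUCUGUAGAGAAGCU",
        "UGUAAGCACCGUCUUUGAAUGCCU",
        "AAAGACGUUGUUGAGGUAAGCACC",
        "AUAACCGAUCUAGAAUGUAAU",
        "UAUUAAACGACCGAUGUAGAAAGU",
        "UAUUAAACGACCGAUGUAGAAAGU",
        "UAUUAAACGACCGAUGUAGAAAGU",
        "UAAAAUAUUAGACUGCUGUACU",
        "AACCGAUGUAGAAUGCUAGACAUU",
        "UCUUGACUUUGGACUUUUGGGU",
        "UAUGUUUGGAUAGAGAAUUUUAAA",
        "CACUUUGGAUUUGAUAUACUU",
        "AACACAAUGGAAUCGUGAUUUCGU",
        "UAGUUUUGAUAUCACUGUCCAAAG",
    ]

    def test_published_candidates_prefer_u_and_a(self):
        table = five_prime_composition(self.PUBLISHED)
        assert table.loc["U", "count"] == 8
        assert table.loc["A", "count"] == 5
        assert table.loc["C", "count"] == 1
        assert table.loc["G", "count"] == 0

    def test_single_candidate(self):
        table = five_prime_composition(["UAUGAAGGCUAGCAUGCAUGC"])
        assert table.loc["U", "count"] == 1

    def test_fractions_sum_to_one(self):
        table = five_prime_composition(self.PUBLISHED)
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            five_prime_composition([])


class TestPlantedRecovery:
    def test_all_planted_novel_hairpins_recovered(self, fourplex):
        truth = fourplex.dataset.truth
        planted = {
            (r.mature, r.locus.chrom, r.locus.strand)
            for r in truth.mirnas.values()
            if r.kind == "novel"
        }
        found = {
            (c.mature, c.locus.chrom, c.locus.strand)
            for c in fourplex.candidates
        }
        assert planted <= found

    def test_no_candidate_from_repeat_region(self, fourplex):
        truth = fourplex.dataset.truth
        lo, hi = truth.rrna_region
        for cand in fourplex.candidates:
            if cand.locus.chrom == truth.rrna_chrom:
                assert cand.locus.end < lo or cand.locus.start > hi

    def test_candidate_counts_equal_planted_abundances(self, fourplex):
        truth = fourplex.dataset.truth
        for cand in fourplex.candidates:
            for lib in truth.config.library_ids:
                expected = truth.seq_counts(lib).get(cand.mature, 0)
                assert cand.counts.get(lib, 0) == expected

    def test_exactly_one_bidirectional_pair(self, fourplex):
        assert len(fourplex.bidirectional_pairs) == 1
        a, b = fourplex.bidirectional_pairs[0]
        assert {a.locus.strand, b.locus.strand} == {"+", "-"}

    def test_conserved_candidate_annotated(self, fourplex):
        truth = fourplex.dataset.truth
        conserved = truth.mirnas["gma-miR-N3"]
        match = [
            c for c in fourplex.candidates if c.mature == conserved.mature
        ]
        assert match and match[0].conserved_to == conserved.conserved_from
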