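"""Windowed search: encoding, candidate passes, heuristics, symmetry."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lodust as ld
from lodust.engine import (
    WindowState,
    _prefix_scores,
    _suffix_scores,
    backward_scan,
    forward_extend,
    kmer_codes,
)

dna = st.text(alphabet="ACGTNacgtn", min_size=0, max_size=80)


class TestEncoding:
    def test_roundtrip_uppercase(self):
        e = ld.EncodedSequence.from_string("s", "ACGTACGT")
        assert e.to_string() == "ACGTACGT"
        assert e.valid.all()

    def test_case_insensitive(self):
        a = ld.EncodedSequence.from_string("s", "acgt")
        b = ld.EncodedSequence.from_string("s", "ACGT")
        assert np.array_equal(a.codes, b.codes)

    def test_ambiguous_bases_masked(self):
        e = ld.EncodedSequence.from_string("s", "ACNGT")
        assert list(e.valid) == [True, True, False, True, True]

    def test_kmer_validity_spans(self):
        e = ld.EncodedSequence.from_string("s", "ACGTNACGTACG")
        _, valid = kmer_codes(e, 4)
        # any 4-mer window touching the N at index 4 is invalid
        assert list(np.nonzero(~valid)[0]) == [1, 2, 3, 4]

    def test_short_sequence(self):
        e = ld.EncodedSequence.from_string("s", "ACG")
        codes, valid = kmer_codes(e, 7)
        assert codes.size == 0 and valid.size == 0


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT")])
    def test_examples(self, seq, expected):
        e = ld.EncodedSequence.from_string("s", seq)
        assert ld.reverse_complement(e).to_string() == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seq=dna)
    def test_involution(self, seq):
        e = ld.EncodedSequence.from_string("s", seq)
        rc2 = ld.reverse_complement(ld.reverse_complement(e))
        assert rc2.to_string() == e.to_string()

    def test_invalid_stays_invalid(self):
        e = ld.EncodedSequence.from_string("s", "ACNGT")
        rc = ld.reverse_complement(e)
        assert list(rc.valid) == [True, True, False, True, True]


class TestBackwardForward:
    def test_candidate_scores_non_increasing(self, tables_small):
        """Candidates in ascending start order carry non-increasing suffix
        scores, by construction of the backward pass."""
        e = ld.EncodedSequence.from_string("h", "A" * 200)
        kcodes, _ = kmer_codes(e, 7)
        state = WindowState(7, 256)
        p = kcodes.size - 1
        state.ws = 0
        np.add.at(state.counts, kcodes[: p + 1], 1)
        cands = backward_scan(state, kcodes, p, tables_small)
        assert len(cands) >= 1
        vs = [c.v for c in cands]
        assert all(a >= b - 1e-12 for a, b in zip(vs, vs[1:]))
        assert all(c.v > 0 for c in cands)

    def test_forward_homopolymer_reaches_end(self, tables_small):
        e = ld.EncodedSequence.from_string("h", "A" * 120)
        kcodes, _ = kmer_codes(e, 7)
        jstar, sstar = forward_extend(kcodes, 0, kcodes.size - 1, tables_small)
        assert jstar == 119
        assert sstar > 0

    def test_forward_stops_at_repeat_end(self, tables_mid):
        """With a random tail appended, the score argmax sits at the end of
        the repeat, so the full interval is rejected as good."""
        rep = ld.tandem_array(ld.RepeatSpec(50, 5, 0.0, seed=1))
        seq = rep + ld.random_dna(100, 0.5, seed=2)
        e = ld.EncodedSequence.from_string("r", seq)
        kcodes, _ = kmer_codes(e, 7)
        jstar, sstar = forward_extend(kcodes, 0, kcodes.size - 1, tables_mid)
        assert len(rep) - 10 <= jstar <= len(rep) + 6
        assert jstar != len(seq) - 1
        # brute-force argmax agreement
        scores = _prefix_scores(kcodes, tables_mid)
        assert sstar == pytest.approx(scores.max())

    def test_single_duplicate_pair_scores_negative(self, tables_mid):
        """One duplicated k-mer cannot overcome 2T of penalty, so a random
        host with a single repeated 7-mer yields nothing."""
        host = ld.random_dna(300, 0.5, seed=33)
        seq = host + host[100:107] + ld.random_dna(50, 0.5, seed=34)
        e = ld.EncodedSequence.from_string("d", seq)
        assert ld.scan_strand(e, tables_mid) == []


class TestScanStrand:
    def test_empty_and_invalid_inputs(self, tables_small):
        assert ld.scan_strand(ld.EncodedSequence.from_string("e", ""), tables_small) == []
        assert ld.scan_strand(ld.EncodedSequence.from_string("e", "ACG"), tables_small) == []
        assert ld.scan_strand(ld.EncodedSequence.from_string("n", "N" * 400), tables_small) == []

    def test_homopolymer_matches_oracle_best(self, model_uniform):
        tables = ld.ScoreTables.build(model_uniform, w=100, T=0.6)
        e = ld.EncodedSequence.from_string("h", "A" * 100)
        merged = ld.scan_strand(e, tables)
        assert len(merged) == 1
        best = max(ld.all_good_intervals(e, tables), key=lambda iv: iv.score)
        assert (merged[0].start, merged[0].end) == (best.start, best.end) == (0, 99)

    def test_dinucleotide_repeat_covered(self, tables_small):
        e = ld.EncodedSequence.from_string("at", "AT" * 50)
        merged = ld.scan_strand(e, tables_small)
        cov = ld.base_union(merged, 100).mean()
        assert cov >= 0.95

    def test_tandem_array_in_host(self, tables_mid):
        """A 50 bp unit repeated 20 times inside 10 kb of random host is
        reported as one covering interval."""
        arr = ld.tandem_array(ld.RepeatSpec(50, 20, 0.0, seed=3))
        host = ld.implant(ld.random_dna(10_000, 0.5, seed=4), arr, 5000)
        e = ld.EncodedSequence.from_string("t", host)
        merged = ld.scan_strand(e, tables_mid)
        cov = ld.base_union(merged, len(host))[5000 : 5000 + len(arr)]
        assert cov.mean() >= 0.95

    def test_window_cap(self, tables_small, fixture_suite):
        """No individually reported interval exceeds the context window."""
        for name, seq in fixture_suite[:10]:
            e = ld.EncodedSequence.from_string(name, seq)
            for iv in ld.scan_strand(e, tables_small, raw=True):
                assert len(iv) <= tables_small.w

    def test_determinism(self, tables_small, fixture_suite):
        name, seq = fixture_suite[2]
        e = ld.EncodedSequence.from_string(name, seq)
        assert ld.scan_strand(e, tables_small) == ld.scan_strand(e, tables_small)

    def test_invalid_bases_split_intervals(self, tables_small):
        seq = "A" * 80 + "N" + "A" * 80
        e = ld.EncodedSequence.from_string("s", seq)
        merged = ld.scan_strand(e, tables_small)
        assert len(merged) == 2
        assert all(iv.end < 80 or iv.start > 80 for iv in merged)


class TestXdrop:
    def test_infinite_x_is_identity(self, tables_mid):
        rep = ld.tandem_array(ld.RepeatSpec(50, 5, 0.0, seed=1))
        seq = rep + ld.random_dna(50, 0.5, seed=77) + rep
        e = ld.EncodedSequence.from_string("x", seq)
        kcodes, _ = kmer_codes(e, 7)
        for iv in ld.scan_strand(e, tables_mid, raw=True):
            assert ld.xdrop_trim(iv, kcodes, tables_mid, math.inf) == iv
            assert ld.xdrop_trim(iv, kcodes, tables_mid, None) == iv

    def test_homopolymer_unchanged(self, tables_mid):
        e = ld.EncodedSequence.from_string("h", "A" * 200)
        for x in (1.0, 20.0):
            merged = ld.scan_strand(e, tables_mid, xdrop=x)
            assert [(iv.start, iv.end) for iv in merged] == [(0, 199)]

    def test_never_widens(self, tables_mid):
        rep = ld.tandem_array(ld.RepeatSpec(50, 5, 0.0, seed=1))
        seq = rep + ld.random_dna(50, 0.5, seed=77) + rep
        e = ld.EncodedSequence.from_string("x", seq)
        kcodes, _ = kmer_codes(e, 7)
        for iv in ld.scan_strand(e, tables_mid, raw=True):
            tr = ld.xdrop_trim(iv, kcodes, tables_mid, 10.0)
            assert tr.start >= iv.start and tr.end <= iv.end

    def test_spacer_removed_at_small_x(self, tables_mid):
        """A 50 bp random spacer between two identical repeat blocks is
        bridged by the definition but excised by X-drop trimming."""
        rep = ld.tandem_array(ld.RepeatSpec(50, 5, 0.0, seed=1))
        spacer = ld.random_dna(50, 0.5, seed=77)
        e = ld.EncodedSequence.from_string("x", rep + spacer + rep)
        with_trim = ld.base_union(ld.scan_strand(e, tables_mid, xdrop=20.0), 550)
        without = ld.base_union(ld.scan_strand(e, tables_mid, xdrop=None), 550)
        assert with_trim.sum() < without.sum()
        assert with_trim[250:300].sum() == 0  # spacer clear
        assert without[250:300].all()  # definitional output bridges it


class TestSymmetryAndMerge:
    def test_merge_adjacent(self):
        ivs = [ld.LCInterval("c", 0, 9, 1.0), ld.LCInterval("c", 10, 19, 2.0)]
        merged = ld.merge_intervals(ivs)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 19)]
        assert merged[0].score == 2.0

    def test_merge_keeps_records_separate(self):
        ivs = [ld.LCInterval("a", 0, 9, 1.0), ld.LCInterval("b", 5, 14, 1.0)]
        assert len(ld.merge_intervals(ivs)) == 2

    def test_symmetric_output_invariant_under_revcomp(self, tables_small, fixture_suite):
        for name, seq in fixture_suite[:6]:
            e = ld.EncodedSequence.from_string(name, seq)
            n = len(seq)
            fwd = ld.scan_symmetric(e, tables_small)
            rev = ld.scan_symmetric(ld.reverse_complement(e), tables_small)
            mapped = sorted((n - 1 - iv.end, n - 1 - iv.start) for iv in rev)
            assert mapped == sorted((iv.start, iv.end) for iv in fwd)

    def test_symmetric_contains_each_strand(self, tables_small, fixture_suite):
        name, seq = fixture_suite[7]
        e = ld.EncodedSequence.from_string(name, seq)
        n = len(seq)
        sym = ld.base_union(ld.scan_symmetric(e, tables_small), n)
        fwd = ld.base_union(ld.scan_strand(e, tables_small), n)
        rev_ivs = ld.scan_strand(ld.reverse_complement(e), tables_small)
        rev = ld.base_union(
            [ld.LCInterval(name, n - 1 - iv.end, n - 1 - iv.start, iv.score) for iv in rev_ivs], n
        )
        assert np.array_equal(sym, fwd | rev)
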