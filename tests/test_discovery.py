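"""Hit merging, flank extraction, TIR/TSD detection and boundary calling."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from passerpipe import (HomologyHit, GenomicInterval, call_boundaries, detect_tir,
                        detect_tsd, discover, extract_flanks, hits_from_truth,
                        merge_hits, revcomp)
from conftest import random_dna


def _hit(chrom, start, end, strand="+", pident=95.0, evalue=1e-150):
    return HomologyHit("q", chrom, start, end, strand, pident, evalue, end - start)


class TestMergeHits:
    def test_overlapping_hits_merge(self):
        loci = merge_hits([_hit("c", 100, 600), _hit("c", 550, 1200)], max_gap=200)
        assert [(l.start, l.end) for l in loci] == [(100, 1200)]

    def test_opposite_strands_stay_separate(self):
        loci = merge_hits([_hit("c", 100, 600, "+"), _hit("c", 100, 600, "-")])
        assert len(loci) == 2
        assert {l.strand for l in loci} == {"+", "-"}

    def test_filters_apply_before_merging(self):
        hits = [_hit("c", 0, 100), _hit("c", 50, 150, evalue=1e-5),
                _hit("c", 120, 200, pident=30.0)]
        loci = merge_hits(hits, max_gap=100, min_identity=80.0, max_evalue=1e-100)
        assert [(l.start, l.end) for l in loci] == [(0, 100)]

    def test_malformed_hit_rejected_not_fatal(self):
        bad = HomologyHit("q", "c", 500, 500, "+", 90.0, 0.0, 0)
        loci = merge_hits([bad, _hit("c", 0, 50)])
        assert [(l.start, l.end) for l in loci] == [(0, 50)]

    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 400)),
                    min_size=1, max_size=25),
           st.integers(0, 300))
    @settings(max_examples=60, deadline=None)
    def test_union_bp_conserved(self, spans, max_gap):
        """Merged loci cover exactly the per-base union when max_gap=0, and at least
        it (bridging only closes gaps) otherwise."""
        hits = [_hit("c", s, s + ln) for s, ln in spans]
        loci = merge_hits(hits, max_gap=max_gap)
        covered = np.zeros(6000, dtype=bool)
        for s, ln in spans:
            covered[s:s + ln] = True
        union_bp = int(covered.sum())
        merged_bp = sum(l.end - l.start for l in loci)
        if max_gap == 0:
            assert merged_bp == union_bp
        else:
            assert merged_bp >= union_bp
        # merged intervals are disjoint and sorted
        starts_ends = sorted((l.start, l.end) for l in loci)
        assert all(a[1] < b[0] or max_gap > 0 for a, b in
                   zip(starts_ends, starts_ends[1:]))


class TestExtractFlanks:
    def test_plus_strand_coordinates(self):
        genome = {"c": random_dna(np.random.default_rng(0), 10_000)}
        loc = extract_flanks(GenomicInterval("c", 2000, 4000, "+"), genome)
        assert loc.left_flank == genome["c"][0:2000]
        assert loc.core_seq == genome["c"][2000:4000]
        assert loc.right_flank == genome["c"][4000:6000]

    def test_edge_truncation(self):
        genome = {"c": random_dna(np.random.default_rng(1), 5000)}
        loc = extract_flanks(GenomicInterval("c", 500, 900, "+"), genome)
        assert len(loc.left_flank) == 500
        assert len(loc.right_flank) == 2000

    def test_minus_strand_is_revcomp_with_swapped_flanks(self):
        genome = {"c": random_dna(np.random.default_rng(2), 9000)}
        plus = extract_flanks(GenomicInterval("c", 3000, 5000, "+"), genome)
        minus = extract_flanks(GenomicInterval("c", 3000, 5000, "-"), genome)
        assert minus.core_seq == revcomp(plus.core_seq)
        assert minus.left_flank == revcomp(plus.right_flank)
        assert minus.right_flank == revcomp(plus.left_flank)

    def test_missing_contig_names_it(self):
        with pytest.raises(KeyError, match="chrX"):
            extract_flanks(GenomicInterval("chrX", 0, 10, "+"), {"c": "ACGT" * 100})


class TestDetectTir:
    def test_planted_perfect_inverted_repeat(self):
        rng = np.random.default_rng(7)
        tir = "CAGGTTGCA"
        elem = tir + random_dna(rng, 500) + revcomp(tir)
        hit = detect_tir(elem, min_len=9)
        assert (hit.length, hit.mismatches) == (9, 0)
        assert (hit.left_offset, hit.right_offset) == (0, 0)
        assert hit.left_seq == tir and revcomp(hit.right_seq) == tir

    def test_mismatched_right_tir_counted(self):
        rng = np.random.default_rng(8)
        tir = random_dna(rng, 28)
        right = list(revcomp(tir))
        right[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[5]]
        right[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[20]]
        # pin the interior boundary bases non-complementary so the repeat cannot
        # extend past the planted 28-mers by chance
        elem = tir + "A" + random_dna(rng, 800) + "A" + "".join(right)
        hit = detect_tir(elem)
        assert (hit.length, hit.mismatches) == (28, 2)

    def test_random_sequence_false_positive_rate(self):
        """<=5% of i.i.d. random 500-mers produce a spurious TIR call."""
        rng = np.random.default_rng(9)
        false_pos = sum(detect_tir(random_dna(rng, 500)) is not None
                        for _ in range(1000))
        assert false_pos <= 50

    def test_symmetric_under_revcomp(self):
        rng = np.random.default_rng(10)
        tir = random_dna(rng, 22)
        elem = tir + random_dna(rng, 400) + revcomp(tir)
        fwd, rev = detect_tir(elem), detect_tir(revcomp(elem))
        assert (fwd.length, fwd.mismatches) == (rev.length, rev.mismatches)
        assert rev.left_seq == revcomp(fwd.right_seq)

    def test_ambiguity_counts_as_mismatch(self):
        tir = "AACCGTAGGCATCCA"
        elem = tir + "G" * 300 + revcomp(tir).replace("C", "N", 1)
        hit = detect_tir(elem, min_len=10)
        assert hit.mismatches >= 1

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            detect_tir("ACGT" * 10)


class TestDetectTsd:
    def test_ta_duplication(self):
        call = detect_tsd("GGGGGGGGTA", "TACCCCCCCC")
        assert (call.sequence, call.length, call.is_ta) == ("TA", 2, True)

    def test_no_duplication(self):
        assert detect_tsd("GGGGGGGG", "CCCCCCCC") is None

    def test_longest_match_wins(self):
        call = detect_tsd("GGGGATTA", "ATTAGGGG")
        assert (call.sequence, call.length, call.is_ta) == ("ATTA", 4, False)

    def test_empty_flank_returns_none(self):
        assert detect_tsd("", "TACCC") is None

    def test_n_blocks_match(self):
        assert detect_tsd("GGGGNA", "NACCCC") is None

    @given(st.text(alphabet="ACGT", min_size=10, max_size=30),
           st.integers(2, 10))
    @settings(max_examples=80, deadline=None)
    def test_exactness(self, flank, k):
        """Whenever a TSD is called, the flank words are bit-identical, and it is
        the longest k (verified by direct enumeration)."""
        word = flank[-min(k, len(flank)):]
        left, right = "CCCC" + flank, word + "GGGG"
        call = detect_tsd(left, right)
        expected = max((kk for kk in range(2, 11)
                        if kk <= min(len(left), len(right))
                        and left[-kk:] == right[:kk]), default=None)
        if expected is None:
            assert call is None
        else:
            assert call.length == expected
            assert left[-call.length:] == right[:call.length] == call.sequence


class TestCallBoundaries:
    def test_planted_truth_recovered(self, planted):
        genome, truth = planted
        hits = hits_from_truth(truth, seed=5)
        copies = discover(genome, hits)
        assert len(copies) == len(truth)
        truth_pairs = set(zip(truth.true_start, truth.true_end))
        found = {(c.element_start, c.element_end) for c in copies}
        assert found == truth_pairs
        for c in copies:
            assert c.tsd is not None and c.tsd.is_ta
            assert c.element_seq.startswith(c.tir.left_seq)
            assert c.element_seq.endswith(c.tir.right_seq)

    def test_deleted_tsd_boundaries_from_tir_alone(self):
        # TIR free of internal TA (and of self-complementary leading dinucleotides)
        # so no mirrored internal TSD decoy exists; the boundaries must come from
        # the inverted repeat alone
        rng = np.random.default_rng(11)
        tir = "CAGGACGCAGCGGAACGGCAGGCCGACG"
        elem = tir + "G" + random_dna(rng, 900) + "G" + revcomp(tir)
        left, right = random_dna(rng, 300), random_dna(rng, 300)
        # no TA duplication around the element; the pinned pads neither pair
        # complementarily (no repeat extension) nor equal each other (no fake TSD)
        region_left = left[:-6] + "GGGGGG"
        region_right = "AAAAAA" + right[6:]
        from passerpipe import CandidateLocus
        locus = CandidateLocus("c", 1000, 1000 + len(elem) - 14, "+",
                               left_flank=region_left + elem[:7],
                               right_flank=elem[-7:] + region_right,
                               core_seq=elem[7:-7])
        copy = call_boundaries(locus)
        assert copy.tir is not None and copy.tir.length == 28
        assert copy.element_seq == elem
        assert copy.tsd is None or not copy.tsd.is_ta

    def test_no_tir_returns_core_with_zero_score(self):
        rng = np.random.default_rng(12)
        from passerpipe import CandidateLocus
        locus = CandidateLocus("c", 500, 1300, "+",
                               left_flank=random_dna(rng, 200),
                               right_flank=random_dna(rng, 200),
                               core_seq=random_dna(rng, 800))
        copy = call_boundaries(locus)
        if copy.tir is None:
            assert (copy.element_start, copy.element_end) == (500, 1300)
            assert copy.boundary_score == 0.0


def test_orientation_equivariance(planted):
    """Discovery on the reverse-complemented genome yields identical elements."""
    genome, truth = planted
    hits = hits_from_truth(truth, seed=6)
    fwd = discover(genome, hits)
    L = len(genome["chr1"])
    genome_rc = {"chr1": revcomp(genome["chr1"])}
    hits_rc = [HomologyHit(h.query_id, h.chrom, L - h.end, L - h.start, "-",
                           h.percent_identity, h.evalue, h.aligned_length)
               for h in hits]
    rev = discover(genome_rc, hits_rc)
    assert sorted(c.element_seq for c in fwd) == sorted(c.element_seq for c in rev)
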