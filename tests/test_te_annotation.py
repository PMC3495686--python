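"""TE-library scanning, coordinate mapping, annotation merge and coverage."""

import numpy as np
import pytest

from conftest import brute_force_te_free_max, random_dna, smith_waterman
from teclassifier import Candidate, TELibraryEntry, build_te_profile, merge_annotations, scan_te
from teclassifier._pairwise import revcomp
from teclassifier.io_formats import AnnotationRecord
from teclassifier.te_annotation import (
    RawFragment,
    TEFragment,
    annotation_fragments_for_candidate,
    map_fragments_to_precursor,
)


def frag(q_start, q_end, name="TE1", source="scan", te_class="DNA", identity=95.0):
    return TEFragment(name, te_class, q_start, q_end, identity, source)


class TestScanTE:
    def test_library_entry_found_at_full_length(self):
        rng = np.random.default_rng(0)
        te = TELibraryEntry("AluY", random_dna(rng, 120), te_class="SINE/Alu")
        frags = scan_te(te.sequence, [te])
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (0, 120)
        assert frags[0].identity_pct == 100.0

    def test_reverse_orientation_detected(self):
        rng = np.random.default_rng(1)
        te = TELibraryEntry("Mariner", random_dna(rng, 100))
        frags = scan_te(revcomp(te.sequence), [te])
        assert len(frags) == 1
        assert frags[0].orientation == "-"

    def test_embedded_mutated_te_overlaps_planted_span(self):
        """60 nt of a TE mutated to ~85% embedded after 50 random nt: the
        reported fragment overlaps the planted span by >= 50 nt, in agreement
        with a full Smith-Waterman oracle."""
        rng = np.random.default_rng(2)
        te = TELibraryEntry("M1", random_dna(rng, 100))
        segment = list(te.sequence[:60])
        for pos in rng.choice(60, size=9, replace=False):
            segment[pos] = rng.choice([b for b in "ACGT" if b != segment[pos]])
        target = random_dna(rng, 50) + "".join(segment)
        frags = scan_te(target, [te])
        assert len(frags) == 1
        overlap = min(frags[0].end, 110) - max(frags[0].start, 50)
        assert overlap >= 50
        oracle_identity, *_ = smith_waterman(target, te.sequence, mismatch=-2.0,
                                             gap_open=-6.0, gap_extend=-4.0)
        assert abs(frags[0].identity_pct - oracle_identity) <= 2.0

    def test_random_sequence_vs_unrelated_library_is_clean(self):
        rng = np.random.default_rng(3)
        library = [TELibraryEntry(f"T{i}", random_dna(rng, 100)) for i in range(5)]
        for _ in range(10):
            assert scan_te(random_dna(rng, 280), library) == []

    def test_two_fragments_of_same_entry_via_masking(self):
        # two copies of the element's ends separated by enough unrelated
        # sequence that a single bridged alignment cannot pay for the middle
        rng = np.random.default_rng(4)
        te = TELibraryEntry("L1", random_dna(rng, 200))
        target = te.sequence[:80] + random_dna(rng, 300) + te.sequence[120:]
        frags = scan_te(target, [te])
        assert len(frags) == 2
        spans = sorted((f.start, f.end) for f in frags)
        assert spans[0][1] <= 90 and spans[1][0] >= 370

    def test_empty_sequence_rejected_empty_library_clean(self):
        with pytest.raises(ValueError):
            scan_te("", [])
        assert scan_te("ACGT" * 30, []) == []


class TestMapFragments:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.cand_seq = random_dna(rng, 100)
        self.left = random_dna(rng, 100)
        self.right = random_dna(rng, 100)
        self.extended = self.left + self.cand_seq + self.right
        self.cand = Candidate("c", self.cand_seq)

    def raw(self, start, end):
        return RawFragment("TE1", "DNA", start, end, 90.0, "+")

    def test_fragment_spanning_candidate_region_maps_to_full_length(self):
        out = map_fragments_to_precursor([self.raw(100, 200)], self.extended, self.cand)
        assert out == [frag(0, 100, identity=90.0)]

    def test_fragment_inside_flank_is_dropped(self):
        out = map_fragments_to_precursor([self.raw(30, 60)], self.extended, self.cand)
        assert out == []

    def test_fragment_straddling_boundary_is_clipped(self):
        out = map_fragments_to_precursor([self.raw(90, 110)], self.extended, self.cand)
        assert len(out) == 1
        assert (out[0].q_start, out[0].q_end) == (0, 10)

    def test_unanchorable_candidate_signals_fallback(self):
        rng = np.random.default_rng(6)
        stranger = Candidate("s", random_dna(rng, 100))
        assert map_fragments_to_precursor([self.raw(0, 50)], self.extended, stranger) is None


class TestAnnotationFragments:
    def test_intersected_and_shifted_into_precursor_coordinates(self):
        from teclassifier.io_formats import GenomicRegion

        cand = Candidate("c", "A" * 100, region=GenomicRegion("chr1", 1000, 1100))
        ann = [
            AnnotationRecord("chr1", 950, 1040, "AluY", "SINE"),
            AnnotationRecord("chr1", 2000, 2100, "L1", "LINE"),
            AnnotationRecord("chr2", 1000, 1100, "L2", "LINE"),
        ]
        frags = annotation_fragments_for_candidate(ann, cand)
        assert len(frags) == 1
        assert (frags[0].q_start, frags[0].q_end, frags[0].source) == (0, 40, "annotation")

    def test_no_coordinates_skips_annotation_path(self):
        cand = Candidate("c", "A" * 100)
        ann = [AnnotationRecord("chr1", 0, 100, "AluY", "SINE")]
        assert annotation_fragments_for_candidate(ann, cand) == []


class TestMergeAnnotations:
    def test_annotation_only(self):
        a = frag(0, 50, source="annotation")
        assert merge_annotations([], [a]) == [a]

    def test_largest_fragment_wins_across_sources(self):
        scan = frag(0, 30, name="A")
        ann = frag(10, 60, name="B", source="annotation")
        profile = build_te_profile(merge_annotations([scan], [ann]), 100)
        assert profile.largest_fragment == ann

    def test_duplicates_collapse_keeping_scan(self):
        s = frag(0, 50)
        a = frag(0, 50, source="annotation")
        merged = merge_annotations([s], [a])
        assert merged == [s]

    def test_both_empty(self):
        assert merge_annotations([], []) == []


class TestBuildTEProfile:
    def test_adjacent_fragments_cover_whole_precursor(self):
        # fragments at display positions 1-54 and 55-89 of an 89-nt precursor
        frags = [frag(0, 54, name="CHARLIE1A"), frag(54, 89, name="ALUSq2")]
        profile = build_te_profile(frags, 89)
        assert profile.coverage_pct == 100.0
        assert profile.te_free_max_nt == 0

    def test_no_fragments(self):
        profile = build_te_profile([], 100)
        assert profile.coverage_pct == 0.0
        assert profile.te_free_max_nt == 100
        assert profile.largest_fragment is None

    def test_terminal_gap_counts(self):
        profile = build_te_profile([frag(0, 40)], 100)
        assert profile.te_free_max_nt == 60
        assert profile.coverage_pct == 40.0

    def test_fragment_beyond_precursor_rejected(self):
        with pytest.raises(ValueError):
            build_te_profile([frag(0, 120)], 100)

    def test_te_free_max_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            length = int(rng.integers(30, 200))
            n = int(rng.integers(0, 6))
            intervals = []
            for _ in range(n):
                s = int(rng.integers(0, length - 1))
                e = int(rng.integers(s + 1, length + 1))
                intervals.append((s, e))
            frags = [frag(s, e) for s, e in intervals]
            profile = build_te_profile(frags, length)
            assert profile.te_free_max_nt == brute_force_te_free_max(intervals, length)
            total = sum(e - s for s, e in intervals)
            assert profile.coverage_pct <= 100.0 * total / length + 1e-9
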