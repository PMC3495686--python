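"""Seed-and-extend search, similar-hit filtering, clustering and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna, smith_waterman
from teclassifier import (
    Candidate,
    GenomicHit,
    Thresholds,
    build_index,
    cluster_hits,
    filter_similar_hits,
    find_hits,
    select_top_hits,
    summarize_hits,
)
from teclassifier._pairwise import revcomp


def make_hit(chrom="chr1", start=0, end=100, strand="+", identity=100.0, score=200.0):
    span = end - start
    return GenomicHit(chrom, start, end, strand, identity, matches=span, aln_len=span, score=score)


class TestBuildIndex:
    def test_position_count_formula(self):
        rng = np.random.default_rng(0)
        idx = build_index({"chr1": random_dna(rng, 1000)}, k=11)
        assert idx.n_positions == 990

    def test_all_n_chromosome_indexes_nothing(self):
        idx = build_index({"chr1": "N" * 2000}, k=11)
        assert idx.n_positions == 0

    def test_two_identical_chromosomes_double_every_kmer(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 500)
        idx = build_index({"chrA": seq, "chrB": seq}, k=11)
        # oracle: naive dictionary build on one copy
        naive: dict[str, int] = {}
        for i in range(len(seq) - 10):
            naive[seq[i : i + 11]] = naive.get(seq[i : i + 11], 0) + 1
        for kmer, count in naive.items():
            assert len(idx.kmer_index[kmer]) == 2 * count

    def test_k_and_genome_validation(self):
        with pytest.raises(ValueError):
            build_index({"chr1": "ACGT" * 100}, k=7)
        with pytest.raises(ValueError):
            build_index({}, k=11)


class TestFindHits:
    def test_exact_substring_gives_one_perfect_hit(self):
        rng = np.random.default_rng(2)
        genome = random_dna(rng, 5000)
        cand = Candidate("probe", genome[2000:2100])
        hits = find_hits(cand, build_index({"chr1": genome}, k=11))
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.chromosome, hit.start, hit.end) == ("chr1", 2000, 2100)
        assert hit.identity_pct == 100.0
        assert hit.strand == "+"

    def test_minus_strand_hit_in_forward_coordinates(self):
        rng = np.random.default_rng(3)
        genome = random_dna(rng, 5000)
        cand = Candidate("probe", revcomp(genome[2000:2100]))
        hits = find_hits(cand, build_index({"chr1": genome}, k=11))
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (2000, 2100)

    def test_planted_mutated_copies_match_smith_waterman_identity(self):
        """Identity of each recovered hit agrees with a full Smith-Waterman
        of the candidate against the planted window within 2 points."""
        rng = np.random.default_rng(4)
        master = random_dna(rng, 100)
        genome = list(random_dna(rng, 5000))
        loci = [500, 2000, 4000]
        for start in loci:
            copy = list(master)
            for pos in rng.choice(100, size=10, replace=False):  # ~90% identity
                copy[pos] = rng.choice([b for b in "ACGT" if b != copy[pos]])
            genome[start : start + 100] = copy
        genome = "".join(genome)
        hits = find_hits(Candidate("m", master), build_index({"chr1": genome}, k=11))
        assert len(hits) == 3
        for hit in hits:
            window = genome[max(0, hit.start - 20) : hit.end + 20]
            oracle_identity, *_ = smith_waterman(window, master)
            assert abs(hit.identity_pct - oracle_identity) <= 2.0

    def test_absent_candidate_yields_no_hits(self):
        # genome over {A,C} and candidate over {A,G}: no shared 11-mer on
        # either strand by construction (revcomp(candidate) is over {C,T})
        rng = np.random.default_rng(5)
        genome = "".join(rng.choice(["A", "C"], 100_000))
        cand = Candidate("absent", "AG" * 50)
        assert find_hits(cand, build_index({"chr1": genome}, k=11)) == []


class TestFilterSimilarHits:
    def test_empty(self):
        assert filter_similar_hits([], 100) == []

    def test_identity_boundary_is_inclusive_at_80(self):
        hits = [make_hit(identity=i) for i in (79.0, 80.0, 81.0)]
        kept = filter_similar_hits(hits, 100)
        assert [h.identity_pct for h in kept] == [80.0, 81.0]

    def test_span_window_drops_oversized_hit(self):
        hit = make_hit(end=125, identity=95.0)  # span 125% of candidate
        assert filter_similar_hits([hit], 100) == []

    def test_span_window_boundaries_inclusive(self):
        hits = [make_hit(end=n) for n in (79, 80, 120, 121)]
        kept = filter_similar_hits(hits, 100)
        assert [h.span for h in kept] == [80, 120]

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.integers(10, 200)), max_size=20
        )
    )
    def test_idempotent_and_monotone_in_thresholds(self, raw):
        hits = [make_hit(end=span, identity=ident) for ident, span in raw]
        strict = Thresholds()
        loose = Thresholds(min_identity_pct=70, size_lo_pct=60, size_hi_pct=140)
        kept = filter_similar_hits(hits, 100, strict)
        assert filter_similar_hits(kept, 100, strict) == kept  # idempotent
        loose_kept = filter_similar_hits(hits, 100, loose)
        assert set(map(id, kept)) <= set(map(id, loose_kept))  # monotone


class TestClusterHits:
    def test_hits_on_two_chromosomes_are_two_clusters(self):
        hits = [make_hit("chr1"), make_hit("chr2")]
        assert len(cluster_hits(hits)) == 2

    def test_separation_exactly_100kb_splits(self):
        hits = [make_hit(end=100), make_hit(start=100_100, end=100_200)]
        assert len(cluster_hits(hits)) == 2

    def test_separation_just_below_100kb_joins(self):
        hits = [make_hit(end=100), make_hit(start=100_099, end=100_199)]
        assert len(cluster_hits(hits)) == 1

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(0, 500_000)),
            min_size=1,
            max_size=15,
        )
    )
    def test_output_is_a_partition_and_maximal(self, raw):
        hits = [make_hit(chrom, start, start + 100) for chrom, start in raw]
        clusters = cluster_hits(hits)
        flat = [h for c in clusters for h in c]
        assert sorted(map(id, flat)) == sorted(map(id, hits))  # partition
        # merging two consecutive clusters would violate the separation rule
        for left, right in zip(clusters, clusters[1:]):
            if left[0].chromosome != right[0].chromosome:
                continue
            gap = min(h.start for h in right) - max(h.end for h in left)
            assert gap >= Thresholds().cluster_min_separation_nt


class TestSummarizeAndSelect:
    def test_32_hits_on_5_chromosomes(self):
        hits = [
            make_hit(f"chr{i % 5}", start=i * 300_000, end=i * 300_000 + 100)
            for i in range(32)
        ]
        s = summarize_hits(hits, hits)
        assert (s.n_similar, s.n_chromosomes_similar) == (32, 5)

    def test_single_self_hit(self):
        hits = [make_hit()]
        s = summarize_hits(hits, hits)
        assert (s.n_hits, s.n_similar, s.n_chromosomes_similar, s.n_clusters) == (1, 1, 1, 1)

    def test_two_distant_hits_two_clusters(self):
        hits = [make_hit(end=100), make_hit(start=150_100, end=150_200)]
        assert summarize_hits(hits, hits).n_clusters == 2

    def test_top_hits_selection_and_tie_break(self):
        hits = [make_hit("chr1", i * 1000, i * 1000 + 100, score=s)
                for i, s in enumerate([50, 90, 70, 90, 60, 40, 80, 30, 20, 10, 5, 95, 85, 65, 55])]
        top = select_top_hits(hits)
        assert len(top) == 10
        assert top[0].score == 95
        scores = [h.score for h in top]
        assert scores == sorted(scores, reverse=True)
        # equal scores resolved by (chromosome, start)
        tied = [h for h in top if h.score == 90]
        assert [h.start for h in tied] == sorted(h.start for h in tied)

    def test_fewer_hits_than_cap_returns_all(self):
        hits = [make_hit(start=i * 1000, end=i * 1000 + 100) for i in range(3)]
        assert len(select_top_hits(hits)) == 3


def test_planted_copy_recovery_across_chromosomes(fixture_genome, fixture_index):
    """Planting copies at ~95% identity across chromosomes: at least 90% are
    recovered as similar hits and every seeded chromosome is seen."""
    master = fixture_genome.te_masters["TE1"].sequence
    hits = find_hits(Candidate("TE1", master), fixture_index)
    similar = filter_similar_hits(hits, len(master))
    planted = [t for t in fixture_genome.truth if t.name == "TE1"]
    assert len(similar) >= 0.9 * len(planted)
    assert {t.chromosome for t in planted} == {h.chromosome for h in similar}
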