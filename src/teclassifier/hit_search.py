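"""Genomic occurrence search: a local seed-and-extend stand-in for a web BLAT.

A k-mer index over the genome provides exact seeds on both strands; seeds on
nearby diagonals are chained and each chained region is resolved with a full
local alignment of the candidate against the surrounding genomic window.
Downstream, hits are filtered to "similar hits" (identity and span windows),
summarized per chromosome, clustered by genomic separation, and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._pairwise import LocalAlignment, align_local, local_aligner, revcomp
from .io_formats import Candidate, Thresholds

__all__ = [
    "GenomeIndex",
    "GenomicHit",
    "HitSummary",
    "SearchParams",
    "build_index",
    "find_hits",
    "filter_similar_hits",
    "cluster_hits",
    "summarize_hits",
    "select_top_hits",
    "hits_to_table",
]


@dataclass
class SearchParams:
    """Tunables of the seed-and-extend search.

    diag_band: seeds whose diagonals differ by at most this are chained.
    window_pad: genomic padding around a chained seed region before extension.
    min_match_frac: a hit must align at least this fraction of the candidate's
        bases identically; weaker chains are discarded.

    Extension scoring is stiff (expected per-column score turns negative
    below 60% identity) so a hit's span reflects the genuinely homologous
    region rather than chance matches in its surroundings.
    """

    diag_band: int = 16
    window_pad: int = 25
    min_match_frac: float = 0.5
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -3.0


@dataclass
class GenomeIndex:
    """Exact k-mer index over a genome; k-mers containing N are skipped."""

    records: dict[str, str]
    k: int
    kmer_index: dict[str, list[tuple[str, int]]] = field(repr=False)

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.kmer_index.values())


@dataclass
class GenomicHit:
    """One aligned occurrence of the candidate in the genome.

    Coordinates are 0-based half-open on the forward genome strand; minus
    strand hits carry strand='-' with forward coordinates.
    """

    chromosome: str
    start: int
    end: int
    strand: str
    identity_pct: float
    matches: int
    aln_len: int
    score: float

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HitSummary:
    """Occurrence statistics feeding the classification rules."""

    n_hits: int
    n_similar: int
    n_chromosomes_similar: int
    n_clusters: int


def build_index(genome_records: dict[str, str], k: int = 11) -> GenomeIndex:
    """Index every exact k-mer of the genome (both strands are searched at
    query time by reverse-complementing the query, so only the forward strand
    is stored)."""
    if k < 8:
        raise ValueError(f"seed length k must be >= 8, got {k}")
    if not genome_records:
        raise ValueError("empty genome: nothing to index")
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome_records.items():
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((chrom, pos))
    return GenomeIndex(records=genome_records, k=k, kmer_index=index)


def _chain_seeds(seeds: list[tuple[str, int, int]], diag_band: int):
    """Group seeds (chrom, diag, tpos) into chains of nearby diagonals."""
    seeds.sort()
    chains: list[list[tuple[str, int, int]]] = []
    for seed in seeds:
        if chains and chains[-1][0][0] == seed[0] and seed[1] - chains[-1][-1][1] <= diag_band:
            chains[-1].append(seed)
        else:
            chains.append([seed])
    return chains


def find_hits(
    candidate: Candidate | str,
    index: GenomeIndex,
    params: SearchParams | None = None,
) -> list[GenomicHit]:
    """Find all genomic occurrences of the candidate on both strands.

    Overlapping hits at the same locus are deduplicated keeping the best
    score, regardless of strand: one genomic interval is one occurrence, and a
    hairpin-shaped candidate otherwise matches its own locus on both strands.
    Hits aligning fewer than ``min_match_frac`` of the candidate's bases are
    dropped. Returns hits sorted by (chromosome, start, strand).
    """
    seq = candidate.sequence if isinstance(candidate, Candidate) else candidate
    params = params or SearchParams()
    k = index.k
    if len(seq) < k:
        raise ValueError(f"candidate shorter than seed length {k}")
    aligner = local_aligner(params.match, params.mismatch, params.gap_open, params.gap_extend)
    raw: list[GenomicHit] = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        seeds: list[tuple[str, int, int]] = []
        for qpos in range(len(q) - k + 1):
            for chrom, tpos in index.kmer_index.get(q[qpos : qpos + k], ()):
                seeds.append((chrom, tpos - qpos, tpos))
        for chain in _chain_seeds(seeds, params.diag_band):
            chrom = chain[0][0]
            target = index.records[chrom]
            wstart = max(0, min(d for _, d, _ in chain) - params.window_pad)
            wend = min(len(target), max(d for _, d, _ in chain) + len(q) + params.window_pad)
            aln = align_local(target[wstart:wend], q, aligner)
            if aln is None or aln.matches < params.min_match_frac * len(seq):
                continue
            raw.append(
                GenomicHit(
                    chromosome=chrom,
                    start=wstart + aln.target_start,
                    end=wstart + aln.target_end,
                    strand=strand,
                    identity_pct=aln.identity_pct,
                    matches=aln.matches,
                    aln_len=aln.aln_len,
                    score=aln.score,
                )
            )
    # deduplicate overlapping hits at the same locus (any strand), best score wins
    raw.sort(key=lambda h: (-h.score, h.chromosome, h.start))
    kept: list[GenomicHit] = []
    for hit in raw:
        clash = any(
            other.chromosome == hit.chromosome
            and hit.start < other.end
            and other.start < hit.end
            for other in kept
        )
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: (h.chromosome, h.start, h.strand))
    return kept


def filter_similar_hits(
    hits: list[GenomicHit], candidate_len: int, thresholds: Thresholds | None = None
) -> list[GenomicHit]:
    """Keep "similar hits": identity >= 80% and span within 80-120% of the
    candidate length, both comparisons inclusive. Order is preserved."""
    t = thresholds or Thresholds()
    if candidate_len < 1:
        raise ValueError("candidate length must be >= 1")
    out = []
    for hit in hits:
        size_pct = 100.0 * hit.span / candidate_len
        if hit.identity_pct >= t.min_identity_pct and t.size_lo_pct <= size_pct <= t.size_hi_pct:
            out.append(hit)
    return out


def cluster_hits(
    similar_hits: list[GenomicHit], thresholds: Thresholds | None = None
) -> list[list[GenomicHit]]:
    """Partition similar hits into clusters.

    Two hits share a cluster iff they lie on the same chromosome and the gap
    between their spans (end-of-left to start-of-right; overlap counts as 0)
    is less than the minimum cluster separation, closed transitively. A
    separation of exactly the threshold therefore splits clusters.
    """
    t = thresholds or Thresholds()
    ordered = sorted(similar_hits, key=lambda h: (h.chromosome, h.start, h.end))
    clusters: list[list[GenomicHit]] = []
    cur_chrom: str | None = None
    cur_max_end = 0
    for hit in ordered:
        gap = max(0, hit.start - cur_max_end)
        if clusters and hit.chromosome == cur_chrom and gap < t.cluster_min_separation_nt:
            clusters[-1].append(hit)
            cur_max_end = max(cur_max_end, hit.end)
        else:
            clusters.append([hit])
            cur_chrom = hit.chromosome
            cur_max_end = hit.end
    return clusters


def summarize_hits(
    hits: list[GenomicHit],
    similar_hits: list[GenomicHit],
    thresholds: Thresholds | None = None,
) -> HitSummary:
    """Count hits, similar hits, chromosomes bearing similar hits and clusters."""
    return HitSummary(
        n_hits=len(hits),
        n_similar=len(similar_hits),
        n_chromosomes_similar=len({h.chromosome for h in similar_hits}),
        n_clusters=len(cluster_hits(similar_hits, thresholds)),
    )


def select_top_hits(
    similar_hits: list[GenomicHit], thresholds: Thresholds | None = None
) -> list[GenomicHit]:
    """The ten (by default) best similar hits by score; ties broken by
    (chromosome, start) ascending."""
    t = thresholds or Thresholds()
    ranked = sorted(similar_hits, key=lambda h: (-h.score, h.chromosome, h.start))
    return ranked[: t.top_n_hits]


def hits_to_table(hits: list[GenomicHit]):
    """Hit dump as a DataFrame with 1-based inclusive display coordinates."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chromosome": h.chromosome,
                "start": h.start + 1,
                "end": h.end,
                "strand": h.strand,
                "identity_pct": round(h.identity_pct, 2),
                "span": h.span,
                "score": h.score,
            }
            for h in hits
        ],
        columns=["chromosome", "start", "end", "strand", "identity_pct", "span", "score"],
    )
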