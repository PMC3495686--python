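"""Shared pairwise-alignment helpers built on Bio.Align.

All local alignments in the pipeline use the same DNA scoring (match +2,
mismatch -1, gap open -5, gap extend -1) with N scoring as a mismatch against
everything, including itself — an N can therefore never contribute a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

MATCH = 2.0
MISMATCH = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = -1.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def _dna_matrix(match: float, mismatch: float):
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = match if a == b else mismatch
    for x in "ACGTN":
        m[x, "N"] = mismatch
        m["N", x] = mismatch
    return m


@lru_cache(maxsize=None)
def local_aligner(
    match: float = MATCH,
    mismatch: float = MISMATCH,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _dna_matrix(match, mismatch)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    """Summary of the best local alignment of a query against a target."""

    target_start: int
    target_end: int
    query_start: int
    query_end: int
    matches: int
    aln_len: int
    score: float
    # aligned blocks as ((target_start, target_end), (query_start, query_end)) pairs
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.aln_len if self.aln_len else 0.0


def align_local(target: str, query: str, aligner: Align.PairwiseAligner | None = None) -> LocalAlignment | None:
    """Best local alignment of query within target, or None when nothing aligns."""
    if not target or not query:
        return None
    aligner = aligner or local_aligner()
    alignments = aligner.align(target, query)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    t_gapped, q_gapped = aln[0], aln[1]
    matches = sum(
        1 for a, b in zip(t_gapped, q_gapped) if a == b and a in "ACGT"
    )
    t_blocks, q_blocks = aln.aligned
    blocks = tuple(
        ((int(tb[0]), int(tb[1])), (int(qb[0]), int(qb[1])))
        for tb, qb in zip(t_blocks, q_blocks)
    )
    return LocalAlignment(
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        matches=matches,
        aln_len=len(t_gapped),
        score=float(aln.score),
        blocks=blocks,
    )
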