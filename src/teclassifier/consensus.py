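"""Flank extension, progressive multiple alignment, and consensus calling.

Each selected genomic hit is extended by flanking genomic sequence (100 nt on
each side by default, clipped at chromosome ends), the extended occurrences
are aligned with a progressive multiple aligner (all-pairs edit distances ->
UPGMA guide tree -> profile-profile merges under affine gap scoring), and a
per-column majority consensus is called: a column emits the most frequent
nucleotide when it occurs at least five times (or in all rows when fewer than
five are aligned) and 'N' otherwise; columns where the gap symbol strictly
dominates are dropped so the consensus stays a plausible genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._pairwise import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH, revcomp
from .hit_search import GenomicHit
from .io_formats import Thresholds

__all__ = [
    "ExtendedOccurrence",
    "Consensus",
    "extend_hit",
    "align_occurrences",
    "build_consensus",
]

_ALPHABET = "ACGT-"
_CHAR_TO_IDX = {c: i for i, c in enumerate(_ALPHABET)}


@dataclass
class ExtendedOccurrence:
    """A genomic hit plus its flanking sequence, strand-normalized so the
    occurrence reads in the candidate's orientation."""

    hit: GenomicHit
    sequence: str
    left_flank_used: int
    right_flank_used: int


@dataclass
class Consensus:
    """Majority consensus over aligned occurrences.

    support[i] is the count of the winning nucleotide at emitted position i;
    column_map[i] is the alignment column it came from.
    """

    sequence: str
    support: list[int]
    column_map: list[int]
    n_rows: int


def extend_hit(hit: GenomicHit, genome: dict[str, str], thresholds: Thresholds | None = None) -> ExtendedOccurrence:
    """Fetch the hit plus up to flank_nt of genomic sequence on each side.

    Flanks are clipped at record boundaries. Minus-strand hits are
    reverse-complemented after extraction, so the reported left flank is 5' of
    the occurrence as it aligns to the candidate.
    """
    t = thresholds or Thresholds()
    if hit.chromosome not in genome:
        raise ValueError(f"hit chromosome {hit.chromosome!r} absent from genome")
    chrom_seq = genome[hit.chromosome]
    left = min(t.flank_nt, hit.start)
    right = min(t.flank_nt, len(chrom_seq) - hit.end)
    seq = chrom_seq[hit.start - left : hit.end + right]
    if hit.strand == "-":
        seq = revcomp(seq)
        left, right = right, left
    return ExtendedOccurrence(hit=hit, sequence=seq, left_flank_used=left, right_flank_used=right)


def _profile_freqs(rows: list[str], n_total: int) -> np.ndarray:
    """Column frequency matrix (L x 5) over A,C,G,T,- ; N contributes nothing."""
    arr = np.zeros((len(rows[0]), 5), dtype=np.float64)
    for row in rows:
        for j, c in enumerate(row):
            idx = _CHAR_TO_IDX.get(c)
            if idx is not None:
                arr[j, idx] += 1.0
    return arr / n_total


# Column-vs-column scoring: nucleotide pairs use match/mismatch, a nucleotide
# against a pre-existing gap costs one gap extension, gap-gap is neutral.
_SUB5 = np.full((5, 5), MISMATCH)
np.fill_diagonal(_SUB5, MATCH)
_SUB5[4, :] = GAP_EXTEND
_SUB5[:, 4] = GAP_EXTEND
_SUB5[4, 4] = 0.0


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two alignment profiles (Gotoh), returning
    the two input row sets padded to a common column layout."""
    fa = _profile_freqs(rows_a, len(rows_a))
    fb = _profile_freqs(rows_b, len(rows_b))
    n, m = fa.shape[0], fb.shape[0]
    S = fa @ _SUB5 @ fb.T  # (n, m) column-pair scores
    go, ge = GAP_OPEN, GAP_EXTEND
    neg = -1e30
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap column inserted into B (moves in A)
    Y = np.full((n + 1, m + 1), neg)  # gap column inserted into A (moves in B)
    M[0, 0] = 0.0
    idx = np.arange(1, m + 1)
    Y[0, 1:] = go + ge * idx
    col = np.arange(1, n + 1)
    X[1:, 0] = go + ge * col
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] + go + ge, X[i - 1, 1:] + ge)
        # Y within-row recursion unrolled: Y[i,j] = go + ge*j + max_{k<j}(M[i,k] - ge*k)
        run = np.maximum.accumulate(M[i, :-1] - ge * np.arange(m))
        Y[i, 1:] = go + ge * idx + run
    # traceback; tie preference: diagonal (M), then up (X), then left (Y)
    ops: list[str] = []
    i, j = n, m
    eps = 1e-9
    vals = (M[n, m], X[n, m], Y[n, m])
    state = "MXY"[int(np.argmax(vals))]
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = "MXY"[int(np.argmax((M[i, j], X[i, j], Y[i, j])))]
        elif state == "X":
            ops.append("U")
            state = "M" if M[i - 1, j] + go + ge >= X[i - 1, j] + ge - eps else "X"
            i -= 1
        else:  # Y
            ops.append("L")
            state = "M" if M[i, j - 1] + go + ge >= Y[i, j - 1] + ge - eps else "Y"
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    pa = pb = 0
    for op in ops:
        if op == "D":
            for r, row in enumerate(rows_a):
                out_a[r] += row[pa]
            for r, row in enumerate(rows_b):
                out_b[r] += row[pb]
            pa += 1
            pb += 1
        elif op == "U":
            for r, row in enumerate(rows_a):
                out_a[r] += row[pa]
            for r in range(len(rows_b)):
                out_b[r] += "-"
            pa += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[pb]
            pb += 1
    return out_a, out_b


def align_occurrences(sequences: list[str]) -> list[str]:
    """Progressive multiple alignment of two or more sequences.

    All-pairs edit distances (edlib, normalized by the longer sequence) feed a
    UPGMA guide tree; profiles are merged progressively along the tree with
    affine-gap profile alignment. Deterministic for a fixed input list; each
    returned row, with gaps removed, reproduces its input sequence exactly.
    """
    if len(sequences) < 2:
        raise ValueError("multiple alignment needs at least 2 sequences")
    n = len(sequences)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(sequences[i], sequences[j], mode="NW", task="distance")["editDistance"]
            dist[i, j] = dist[j, i] = d / max(len(sequences[i]), len(sequences[j]))
    tree = linkage(squareform(dist, checks=False), method="average")
    # clusters[cid] = (row indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [sequences[i]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(tree):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        out_a, out_b = _align_profiles(rows_a, rows_b)
        clusters[n + step] = (idx_a + idx_b, out_a + out_b)
    (_, (order, rows)) = clusters.popitem()
    result = [""] * n
    for pos, row in zip(order, rows):
        result[pos] = row
    assert all(result)
    for seq, row in zip(sequences, result):
        if row.replace("-", "") != seq:
            raise AssertionError("alignment row does not reproduce its input sequence")
    return result


def build_consensus(alignment: list[str], thresholds: Thresholds | None = None) -> Consensus:
    """Call the per-column majority consensus of an alignment.

    Per column: when the gap symbol is strictly the most frequent symbol and
    reaches the effective threshold the column is omitted; otherwise the most
    frequent nucleotide is emitted when its count reaches the effective
    threshold (ties broken alphabetically) and 'N' when it does not. The
    effective threshold is min(consensus_min_count, number of rows) so the
    rule degrades to unanimity for small alignments.
    """
    if not alignment:
        raise ValueError("empty alignment")
    t = thresholds or Thresholds()
    n_rows = len(alignment)
    eff = min(t.consensus_min_count, n_rows)
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("alignment rows differ in length")
    seq: list[str] = []
    support: list[int] = []
    column_map: list[int] = []
    for col in range(width):
        counts = {c: 0 for c in "ACGT"}
        gap = 0
        for row in alignment:
            c = row[col]
            if c == "-":
                gap += 1
            elif c in counts:
                counts[c] += 1
        best_nt = max("ACGT", key=lambda c: counts[c])  # alphabetical tie-break
        if gap >= eff and gap > counts[best_nt]:
            continue  # gap-majority column: deleted from the consensus
        if counts[best_nt] >= eff:
            seq.append(best_nt)
            support.append(counts[best_nt])
        else:
            seq.append("N")
            support.append(counts[best_nt])
        column_map.append(col)
    return Consensus(sequence="".join(seq), support=support, column_map=column_map, n_rows=n_rows)
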