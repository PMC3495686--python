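"""Repeat-library scanning and TE coverage profiling of a precursor.

The consensus built from the genomic occurrences (and the raw candidate
itself) is scanned against a TE library with local alignment in both
orientations; qualifying matches are transported into precursor coordinates,
merged with any external repeat annotations, and summarized as a coverage
profile whose key quantity is the longest TE-free run of precursor positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._pairwise import LocalAlignment, align_local, local_aligner, revcomp
from .io_formats import AnnotationRecord, Candidate, TELibraryEntry

__all__ = [
    "ScanParams",
    "RawFragment",
    "TEFragment",
    "TEProfile",
    "scan_te",
    "map_fragments_to_precursor",
    "annotation_fragments_for_candidate",
    "merge_annotations",
    "build_te_profile",
    "fragments_to_table",
]


@dataclass
class ScanParams:
    """Library-scan acceptance thresholds and scoring.

    A local alignment of a library entry against the scanned sequence is
    reported when its identity reaches min_identity_pct and the matched
    segment on the scanned sequence spans at least min_len nucleotides.
    Chosen to detect diverged (~70% identity) TE copies while rejecting the
    short perfect matches expected between random sequences.

    The scan scoring is stiffer than the pipeline's alignment scoring: with
    match +2 / mismatch -2 the expected per-column score turns negative below
    50% identity, so a local alignment cannot profitably extend through
    sequence unrelated to the element; the strong gap costs prevent stitching
    chance match runs across unrelated segments.
    """

    min_identity_pct: float = 60.0
    min_len: int = 20
    max_fragments_per_entry: int = 4
    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -4.0
    # Score floor excluding chance matches: the best local alignment between
    # unrelated ~100-300 nt sequences stays below ~30 under this scoring,
    # while a genuine fragment (>=50 nt at 70% identity, or >=20 nt
    # near-perfect) clears 40 comfortably.
    min_score: float = 40.0


@dataclass(frozen=True)
class RawFragment:
    """A library match in scanned-sequence coordinates (before mapping)."""

    te_name: str
    te_class: str
    start: int
    end: int
    identity_pct: float
    orientation: str


@dataclass(frozen=True)
class TEFragment:
    """A TE match mapped onto precursor coordinates (0-based half-open)."""

    te_name: str
    te_class: str
    q_start: int
    q_end: int
    identity_pct: float
    source: str  # "scan" or "annotation"

    @property
    def span(self) -> int:
        return self.q_end - self.q_start


@dataclass
class TEProfile:
    """TE content of a precursor: fragments, coverage, longest TE-free run."""

    fragments: list[TEFragment]
    coverage_pct: float
    te_free_max_nt: int
    largest_fragment: TEFragment | None


def scan_te(
    sequence: str,
    te_library: list[TELibraryEntry],
    params: ScanParams | None = None,
) -> list[RawFragment]:
    """Scan a sequence against a TE library with local alignment.

    Both orientations of every entry are tried; after a qualifying fragment is
    found its span is masked with N and the entry is realigned, so multiple
    fragments of the same element can be reported. N never counts as a match.
    """
    if not sequence:
        raise ValueError("empty sequence")
    params = params or ScanParams()
    aligner = local_aligner(params.match, params.mismatch, params.gap_open, params.gap_extend)
    fragments: list[RawFragment] = []
    for entry in te_library:
        for orientation, query in (("+", entry.sequence), ("-", revcomp(entry.sequence))):
            target = sequence
            for _ in range(params.max_fragments_per_entry):
                aln = align_local(target, query, aligner)
                if aln is None:
                    break
                span = aln.target_end - aln.target_start
                if (
                    span < params.min_len
                    or aln.identity_pct < params.min_identity_pct
                    or aln.score < params.min_score
                ):
                    break
                fragments.append(
                    RawFragment(
                        te_name=entry.te_name,
                        te_class=entry.te_class,
                        start=aln.target_start,
                        end=aln.target_end,
                        identity_pct=aln.identity_pct,
                        orientation=orientation,
                    )
                )
                target = target[: aln.target_start] + "N" * span + target[aln.target_end :]
    fragments.sort(key=lambda f: (f.start, f.end, f.te_name))
    return fragments


def _position_map(aln: LocalAlignment) -> dict[int, int]:
    """Scanned-sequence position -> candidate position over aligned blocks."""
    mapping: dict[int, int] = {}
    for (ts, te), (qs, _qe) in aln.blocks:
        for off in range(te - ts):
            mapping[ts + off] = qs + off
    return mapping


def map_fragments_to_precursor(
    raw_fragments: list[RawFragment],
    scanned_sequence: str,
    candidate: Candidate,
    min_anchor_identity_pct: float = 50.0,
) -> list[TEFragment] | None:
    """Transport library matches from the scanned sequence into candidate
    coordinates.

    The candidate is locally aligned to the scanned sequence (the anchor);
    fragment intervals are mapped through the aligned blocks, fragments lying
    entirely in flank regions are dropped and partial overlaps are clipped.
    Returns None when the candidate fails to anchor (identity < 50%), in
    which case the caller should fall back to scanning the candidate
    directly.
    """
    # The candidate plays the query role against the scanned sequence. The
    # anchor uses stiff scoring so it covers only the genuinely homologous
    # segment instead of gap-skipping through unrelated sequence, and must
    # align at least half the candidate's bases: a short chance match is not
    # an anchor even when its own identity is high.
    aln = align_local(scanned_sequence, candidate.sequence, local_aligner(2.0, -3.0, -8.0, -3.0))
    if (
        aln is None
        or aln.identity_pct < min_anchor_identity_pct
        or aln.matches < 0.5 * len(candidate.sequence)
    ):
        return None
    if not raw_fragments:
        return []
    posmap = _position_map(aln)
    out: list[TEFragment] = []
    for frag in raw_fragments:
        mapped = [posmap[p] for p in range(frag.start, frag.end) if p in posmap]
        if not mapped:
            continue
        q_start, q_end = min(mapped), max(mapped) + 1
        out.append(
            TEFragment(
                te_name=frag.te_name,
                te_class=frag.te_class,
                q_start=q_start,
                q_end=q_end,
                identity_pct=frag.identity_pct,
                source="scan",
            )
        )
    return out


def fragments_from_scan(raw_fragments: list[RawFragment]) -> list[TEFragment]:
    """Raw fragments of a directly scanned candidate, as precursor fragments."""
    return [
        TEFragment(f.te_name, f.te_class, f.start, f.end, f.identity_pct, "scan")
        for f in raw_fragments
    ]


def annotation_fragments_for_candidate(
    annotations: list[AnnotationRecord], candidate: Candidate
) -> list[TEFragment]:
    """Intersect external repeat annotations with the candidate's genomic
    region and shift them into precursor coordinates.

    Skipped (empty result) when the candidate carries no coordinates; on the
    minus strand precursor coordinates are mirrored.
    """
    region = candidate.region
    if region is None:
        return []
    out: list[TEFragment] = []
    for rec in annotations:
        if rec.chromosome != region.chromosome:
            continue
        start = max(rec.start, region.start)
        end = min(rec.end, region.end)
        if end <= start:
            continue
        if region.strand == "-":
            q_start = region.end - end
            q_end = region.end - start
        else:
            q_start = start - region.start
            q_end = end - region.start
        out.append(TEFragment(rec.te_name, rec.te_class, q_start, q_end, 100.0, "annotation"))
    return out


def merge_annotations(
    scan_fragments: list[TEFragment], annotation_fragments: list[TEFragment]
) -> list[TEFragment]:
    """Union of library-scan and external-annotation fragments.

    Duplicates (same span and TE name) collapse, keeping the scan copy; the
    union feeds coverage while the single greatest fragment is reported
    separately by the profile.
    """
    merged: dict[tuple[int, int, str], TEFragment] = {}
    for frag in annotation_fragments + scan_fragments:  # scan overwrites duplicates
        merged[(frag.q_start, frag.q_end, frag.te_name)] = frag
    return sorted(merged.values(), key=lambda f: (f.q_start, f.q_end, f.te_name))


def build_te_profile(fragments: list[TEFragment], precursor_len: int) -> TEProfile:
    """Coverage of the precursor by the union of TE fragments and the longest
    run of uncovered positions (including uncovered runs at both ends)."""
    if precursor_len < 1:
        raise ValueError("precursor length must be >= 1")
    for frag in fragments:
        if frag.q_start < 0 or frag.q_end > precursor_len:
            raise ValueError(f"fragment {frag} exceeds precursor length {precursor_len}")
    intervals = sorted((f.q_start, f.q_end) for f in fragments)
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    covered = sum(e - s for s, e in merged)
    gaps = []
    prev = 0
    for s, e in merged:
        gaps.append(s - prev)
        prev = e
    gaps.append(precursor_len - prev)
    largest = None
    if fragments:
        largest = min(
            fragments,
            key=lambda f: (-f.span, 0 if f.source == "scan" else 1, f.q_start),
        )
    return TEProfile(
        fragments=list(fragments),
        coverage_pct=100.0 * covered / precursor_len,
        te_free_max_nt=max(gaps) if gaps else precursor_len,
        largest_fragment=largest,
    )


def fragments_to_table(fragments: list[TEFragment]):
    """Fragment dump as a DataFrame with 1-based inclusive display coordinates."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "te_name": f.te_name,
                "te_class": f.te_class,
                "q_start": f.q_start + 1,
                "q_end": f.q_end,
                "identity_pct": round(f.identity_pct, 2),
                "source": f.source,
            }
            for f in fragments
        ],
        columns=["te_name", "te_class", "q_start", "q_end", "identity_pct", "source"],
    )
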