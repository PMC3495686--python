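"""Per-candidate orchestration of the five pipeline steps, batch mode and reports.

Step order per candidate: genomic search -> similar-hit filter -> summary ->
top-hit selection -> flank extension -> multiple alignment -> consensus ->
TE-library scan -> coordinate mapping -> annotation merge -> coverage profile
-> rule-based classification. Degenerate paths: with a single similar hit the
"consensus" is that hit's extended sequence; with none it is the bare
candidate. The raw candidate is always scanned against the library as well,
so candidates whose genomic mapping fails are still classifiable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classifier import ClassificationResult, classify
from .consensus import align_occurrences, build_consensus, extend_hit
from .hit_search import (
    GenomeIndex,
    SearchParams,
    filter_similar_hits,
    find_hits,
    select_top_hits,
    summarize_hits,
)
from .io_formats import AnnotationRecord, Candidate, Thresholds
from .te_annotation import (
    ScanParams,
    TELibraryEntry,
    annotation_fragments_for_candidate,
    build_te_profile,
    fragments_from_scan,
    map_fragments_to_precursor,
    merge_annotations,
    scan_te,
)

__all__ = ["BatchReport", "run_pipeline", "run_batch", "summarize_interspersion", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class BatchReport:
    """Per-candidate results, per-candidate errors, and the interspersion summary."""

    results: list[ClassificationResult]
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            largest = r.profile.largest_fragment
            rows.append(
                {
                    "candidate": r.candidate_name,
                    "n_hits": r.summary.n_hits,
                    "n_similar": r.summary.n_similar,
                    "n_chromosomes": r.summary.n_chromosomes_similar,
                    "n_clusters": r.summary.n_clusters,
                    "coverage_pct": round(r.profile.coverage_pct, 2),
                    "te_free_max_nt": r.profile.te_free_max_nt,
                    "largest_te": largest.te_name if largest else "",
                    "largest_te_class": largest.te_class if largest else "",
                    "largest_te_span": largest.span if largest else 0,
                    "category": r.category,
                    "rule_fired": r.rule_fired,
                }
            )
        for name, msg in self.errors.items():
            rows.append({"candidate": name, "category": "ERROR", "rule_fired": msg})
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        return summarize_interspersion(self.results)


def run_pipeline(
    candidate: Candidate,
    index: GenomeIndex,
    te_library: list[TELibraryEntry],
    annotations: list[AnnotationRecord] | None = None,
    thresholds: Thresholds | None = None,
    search_params: SearchParams | None = None,
    scan_params: ScanParams | None = None,
) -> ClassificationResult:
    """Run the full classification pipeline for one candidate."""
    t = thresholds or Thresholds()
    try:
        hits = find_hits(candidate, index, search_params)
        similar = filter_similar_hits(hits, len(candidate.sequence), t)
        summary = summarize_hits(hits, similar, t)
        logger.debug("%s: %d hits, %d similar on %d chromosomes", candidate.name,
                     summary.n_hits, summary.n_similar, summary.n_chromosomes_similar)

        top = select_top_hits(similar, t)
        if len(top) >= 2:
            extended = [extend_hit(h, index.records, t) for h in top]
            alignment = align_occurrences([e.sequence for e in extended])
            consensus_seq = build_consensus(alignment, t).sequence
        elif len(top) == 1:
            consensus_seq = extend_hit(top[0], index.records, t).sequence
        else:
            consensus_seq = candidate.sequence
        logger.debug("%s: consensus length %d from %d occurrences",
                     candidate.name, len(consensus_seq), len(top))

        raw_consensus_frags = scan_te(consensus_seq, te_library, scan_params)
        mapped = map_fragments_to_precursor(raw_consensus_frags, consensus_seq, candidate)
        if mapped is None:
            logger.debug("%s: candidate did not anchor in the consensus; direct scan only",
                         candidate.name)
            mapped = []
        direct = fragments_from_scan(scan_te(candidate.sequence, te_library, scan_params))
        ann_frags = annotation_fragments_for_candidate(annotations or [], candidate)
        fragments = merge_annotations(mapped + direct, ann_frags)
        profile = build_te_profile(fragments, len(candidate.sequence))
        logger.debug("%s: %d TE fragments, coverage %.1f%%, longest TE-free run %d nt",
                     candidate.name, len(profile.fragments), profile.coverage_pct,
                     profile.te_free_max_nt)
        return classify(summary, profile, t, candidate_name=candidate.name)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed for candidate {candidate.name!r}: {exc}") from exc


def run_batch(
    candidates: list[Candidate],
    index: GenomeIndex,
    te_library: list[TELibraryEntry],
    annotations: list[AnnotationRecord] | None = None,
    thresholds: Thresholds | None = None,
    search_params: SearchParams | None = None,
    scan_params: ScanParams | None = None,
) -> BatchReport:
    """Independent per-candidate runs; a failing candidate becomes an error
    row instead of aborting the batch."""
    if not candidates:
        raise ValueError("no records")
    results: list[ClassificationResult] = []
    errors: dict[str, str] = {}
    for cand in candidates:
        try:
            results.append(
                run_pipeline(cand, index, te_library, annotations, thresholds,
                             search_params, scan_params)
            )
        except Exception as exc:
            logger.warning("candidate %s failed: %s", cand.name, exc)
            errors[cand.name] = str(exc)
    return BatchReport(results=results, errors=errors)


def summarize_interspersion(results: list[ClassificationResult]) -> pd.DataFrame:
    """Count candidates per (similar-hit bin x chromosome bin x category).

    Bins follow the field's reporting convention: a single similar hit on one
    chromosome, several hits on one chromosome, several hits on several
    chromosomes. Empty cells are reported as 0.
    """
    if not results:
        raise ValueError("no results to summarize")
    bins = [
        "1 similar hit, 1 chromosome",
        "several similar hits, 1 chromosome",
        "several similar hits, several chromosomes",
    ]
    categories = ["BONA_FIDE", "TE_DERIVED", "TE"]
    counts = {b: {c: 0 for c in categories} for b in bins}
    for r in results:
        if r.summary.n_similar <= 1:
            b = bins[0]
        elif r.summary.n_chromosomes_similar <= 1:
            b = bins[1]
        else:
            b = bins[2]
        counts[b][r.category] += 1
    frame = pd.DataFrame(
        [{"bin": b, **counts[b]} for b in bins], columns=["bin", *categories]
    )
    return frame


def write_report(report: BatchReport, prefix: str | Path) -> None:
    """Write the per-candidate TSV, its JSON mirror, and the summary TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(
            {
                "results": frame.to_dict(orient="records"),
                "summary": report.summary_table().to_dict(orient="records") if report.results else [],
            },
            fh,
            indent=2,
        )
    if report.results:
        report.summary_table().to_csv(f"{prefix}.summary.tsv", sep="\t", index=False)
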