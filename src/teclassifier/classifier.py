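"""The rule-based classification of a precursor candidate.

Three categories are distinguished from the occurrence statistics and the TE
coverage profile:

* ``BONA_FIDE`` — a genuine precursor ncRNA: essentially unique in the genome
  and free of recognizable TE sequence;
* ``TE_DERIVED`` — partially TE: either a TE-free segment long enough to host
  a mature small RNA remains, or the candidate is repeated/dispersed beyond
  the copy-number or chromosome thresholds without recognizable TE sequence;
* ``TE`` — a mis-annotated transposable element: no TE-free segment of mature
  size remains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hit_search import HitSummary
from .io_formats import Thresholds
from .te_annotation import TEProfile

__all__ = ["Category", "ClassificationResult", "classify"]

BONA_FIDE = "BONA_FIDE"
TE_DERIVED = "TE_DERIVED"
TE = "TE"
Category = str


@dataclass
class ClassificationResult:
    """Final category plus all the evidence used to reach it."""

    candidate_name: str
    category: Category
    rule_fired: str
    summary: HitSummary
    profile: TEProfile
    thresholds_used: Thresholds


def classify(
    summary: HitSummary,
    profile: TEProfile,
    thresholds: Thresholds | None = None,
    candidate_name: str = "",
) -> ClassificationResult:
    """Apply the five classification rules; exactly one fires.

    TE-evidence rules take precedence over repetition rules:

    R5  fragments present, longest TE-free segment < 24 nt  -> TE
    R4  fragments present, longest TE-free segment >= 24 nt -> TE_DERIVED
    R2  no fragment, >= 20 similar hits                     -> TE_DERIVED
    R3  no fragment, similar hits on >= 6 chromosomes       -> TE_DERIVED
    R1  otherwise                                           -> BONA_FIDE

    All thresholds are inclusive and configurable.
    """
    t = thresholds or Thresholds()
    if profile.fragments:
        if profile.te_free_max_nt < t.te_free_min_nt:
            category, rule = TE, "R5"
        else:
            category, rule = TE_DERIVED, "R4"
    elif summary.n_similar >= t.min_similar_hits:
        category, rule = TE_DERIVED, "R2"
    elif summary.n_chromosomes_similar >= t.min_chromosomes:
        category, rule = TE_DERIVED, "R3"
    else:
        category, rule = BONA_FIDE, "R1"
    return ClassificationResult(
        candidate_name=candidate_name,
        category=category,
        rule_fired=rule,
        summary=summary,
        profile=profile,
        thresholds_used=t,
    )
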