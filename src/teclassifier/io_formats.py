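"""Readers, writers and configuration for every external format the pipeline touches.

Supported formats: FASTA (candidates, genomes, TE libraries), RepeatMasker
``.out`` tables, BED4 intervals, per-candidate 5'-read-count TSV tables and a
flat-key YAML configuration file for the classification thresholds.

Coordinate convention: everything held in memory is 0-based half-open on the
forward strand; report writers convert to 1-based inclusive for display.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "GenomicRegion",
    "Candidate",
    "TELibraryEntry",
    "AnnotationRecord",
    "Thresholds",
    "read_fasta",
    "read_te_library",
    "read_genome",
    "write_fasta",
    "read_repeatmasker_out",
    "read_bed",
    "read_read_counts",
    "load_config",
]

# Uppercase IUPAC nucleotide codes (plus U); anything else in a record is an error.
_IUPAC = set("ACGTUNRYSWKMBDHV")
# Ambiguity codes other than N are collapsed to N: downstream alignment only
# distinguishes the four bases and the "unknown" symbol.
_AMBIG = set("RYSWKMBDHV")

_REGION_RE = re.compile(r"region=([\w.>-]+):(\d+)-(\d+)(?:\(([+-])\))?")


def normalize_sequence(seq: str, *, name: str = "?") -> str:
    """Uppercase, U->T, ambiguity codes -> N; reject non-IUPAC characters."""
    up = seq.upper()
    bad = set(up) - _IUPAC
    if bad:
        raise ValueError(
            f"illegal characters {sorted(bad)!r} in record {name!r}: not IUPAC nucleotide codes"
        )
    table = str.maketrans({"U": "T", **{c: "N" for c in _AMBIG}})
    return up.translate(table)


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open, with strand."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region end must exceed start: {self}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Candidate:
    """A hairpin precursor sequence under test, with optional genomic coordinates."""

    name: str
    sequence: str
    region: GenomicRegion | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("candidate name must be non-empty")
        self.sequence = normalize_sequence(self.sequence, name=self.name)
        if len(self.sequence) < 1:
            raise ValueError(f"candidate {self.name!r} has an empty sequence")


@dataclass
class TELibraryEntry:
    """One repeat-library consensus, with a RepeatMasker-style class label."""

    te_name: str
    sequence: str
    te_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.te_name:
            raise ValueError("TE name must be non-empty")
        self.sequence = normalize_sequence(self.sequence, name=self.te_name)
        if len(self.sequence) < 1:
            raise ValueError(f"TE library entry {self.te_name!r} has an empty sequence")


@dataclass(frozen=True)
class AnnotationRecord:
    """An external repeat annotation on the genome (RepeatMasker .out or BED)."""

    chromosome: str
    start: int
    end: int
    te_name: str
    te_class: str = "unknown"
    source: str = "annotation"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"annotation end must exceed start: {self}")


@dataclass
class Thresholds:
    """The classification constants of the pipeline, all overridable.

    min_identity_pct
        Minimum percent identity between a genomic hit and the candidate for
        the hit to count as a "similar hit".
    size_lo_pct, size_hi_pct
        A similar hit's genomic span must fall between these percentages of
        the candidate length (both bounds inclusive).
    min_similar_hits
        A candidate with at least this many similar hits and no recognizable
        TE fragment is called TE-derived.
    min_chromosomes
        A candidate whose similar hits appear on at least this many
        chromosomes, with no recognizable TE fragment, is called TE-derived.
    flank_nt
        Nucleotides of genomic context fetched on each side of a hit before
        the occurrences are aligned.
    top_n_hits
        Number of best similar hits used to build the consensus.
    consensus_min_count
        A consensus column emits a nucleotide only when the most frequent
        nucleotide occurs at least this many times; otherwise N.
    te_free_min_nt
        A precursor bearing TE fragments is TE-derived when a TE-free segment
        at least this long remains (the length of a mature mi/siRNA), and a
        mis-annotated TE otherwise.
    cluster_min_separation_nt
        Two same-chromosome occurrences separated by at least this many
        nucleotides fall in different clusters.
    """

    min_identity_pct: float = 80.0
    size_lo_pct: float = 80.0
    size_hi_pct: float = 120.0
    min_similar_hits: int = 20
    min_chromosomes: int = 6
    flank_nt: int = 100
    top_n_hits: int = 10
    consensus_min_count: int = 5
    te_free_min_nt: int = 24
    cluster_min_separation_nt: int = 100_000

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "flank_nt":
                if v < 0:  # zero disables extension
                    raise ValueError(f"flank_nt must be non-negative, got {v}")
            elif v <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive, got {v}")
        if self.size_lo_pct >= self.size_hi_pct:
            raise ValueError("size_lo_pct must be below size_hi_pct")

    def replace(self, **overrides) -> "Thresholds":
        return dataclasses.replace(self, **overrides)


def _parse_region(description: str) -> GenomicRegion | None:
    """Extract an optional ``region=chr:start-end(strand)`` header tag.

    The tag uses the familiar 1-based inclusive display convention and is
    converted to the internal 0-based half-open one.
    """
    m = _REGION_RE.search(description)
    if m is None:
        return None
    chrom, start1, end1, strand = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
    return GenomicRegion(chrom, start1 - 1, end1, strand or "+")


def read_fasta(path: str | Path) -> list[Candidate]:
    """Read candidate precursors from FASTA.

    Sequences are uppercased with U normalized to T; an optional
    ``region=chr:start-end(strand)`` tag in the description attaches genomic
    coordinates. Duplicate record names and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    seen: set[str] = set()
    out: list[Candidate] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record name {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(Candidate(rec.id, str(rec.seq), region=_parse_region(rec.description)))
    return out


def read_te_library(path: str | Path) -> list[TELibraryEntry]:
    """Read a TE library FASTA; ``name#class/family`` headers set the class."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    seen: set[str] = set()
    out: list[TELibraryEntry] = []
    for rec in records:
        name, _, te_class = rec.id.partition("#")
        if name in seen:
            raise ValueError(f"duplicate record name {name!r} in {path}")
        seen.add(name)
        out.append(TELibraryEntry(name, str(rec.seq), te_class=te_class or "unknown"))
    return out


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a multi-record genome FASTA into a chromosome -> sequence mapping."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    genome: dict[str, str] = {}
    for rec in records:
        if rec.id in genome:
            raise ValueError(f"duplicate record name {rec.id!r} in {path}")
        genome[rec.id] = normalize_sequence(str(rec.seq), name=rec.id)
    return genome


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records to FASTA.

    Accepts Candidate / TELibraryEntry objects, ``(name, sequence)`` pairs, or
    a mapping (e.g. a genome dict).
    """
    if isinstance(records, Mapping):
        records = list(records.items())
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, Candidate):
                name, seq = rec.name, rec.sequence
            elif isinstance(rec, TELibraryEntry):
                name = rec.te_name if rec.te_class == "unknown" else f"{rec.te_name}#{rec.te_class}"
                seq = rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_repeatmasker_out(path: str | Path) -> list[AnnotationRecord]:
    """Parse a RepeatMasker ``.out`` annotation table.

    The format carries three header lines followed by whitespace-delimited
    columns; genomic begin/end are 1-based inclusive and converted to the
    internal 0-based half-open convention.
    """
    out: list[AnnotationRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        cols = stripped.split()
        # header lines: "SW perc perc perc query ..." / "score div. del. ins. ..."
        if cols[0] in {"SW", "score", "bit"} or not cols[0][0].isdigit():
            if lineno <= 3:
                continue
        try:
            chrom = cols[4]
            start = int(cols[5]) - 1
            end = int(cols[6])
            te_name = cols[9]
            te_class = cols[10]
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed RepeatMasker line {lineno}: {stripped!r}") from exc
        out.append(AnnotationRecord(chrom, start, end, te_name, te_class))
    return out


def read_bed(path: str | Path) -> list[AnnotationRecord]:
    """Parse BED4 repeat intervals (already 0-based half-open)."""
    out: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("track", "browser", "#")):
                continue
            cols = stripped.split()
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                name = cols[3] if len(cols) > 3 else "repeat"
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {stripped!r}") from exc
            te_name, _, te_class = name.partition("#")
            out.append(AnnotationRecord(chrom, start, end, te_name, te_class or "unknown"))
    return out


def read_read_counts(path: str | Path) -> dict[str, dict[int, int]]:
    """Read a per-candidate 5'-start read-count TSV.

    Columns: candidate, offset (5'-start position), count. Returns a mapping
    candidate -> {offset: count}.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (candidate, offset, count)")
    df.columns = ["candidate", "offset", "count", *df.columns[3:]]
    counts: dict[str, dict[int, int]] = {}
    for name, sub in df.groupby("candidate", sort=False):
        counts[str(name)] = dict(zip(sub["offset"].astype(int), sub["count"].astype(int)))
    return counts


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> Thresholds:
    """Build Thresholds from defaults, an optional flat-key YAML file, and overrides.

    Unknown keys are an error; non-positive values are rejected by the
    Thresholds validator.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"{path}: config must be a flat key: value mapping")
        values.update(loaded)
    if overrides:
        values.update(overrides)
    known = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**values)
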