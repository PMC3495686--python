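"""Deterministic synthetic genomes, TE libraries and labeled candidates.

The generator emulates the situation the classifier is built for: a genome of
i.i.d. uniform background sequence carrying planted copies of TE master
sequences (mutated by per-base substitutions, random strand) and unique
hairpin loci, plus candidates of the three truth categories:

* ``bona_fide``  — a unique hairpin planted at a single locus;
* ``te``         — a copy of a planted TE master (entirely TE by construction);
* ``te_derived`` — a TE segment concatenated with a unique tail of mature-RNA
  size or larger, so a TE-free segment survives by construction.

Identical spec + seed reproduce identical genome bytes, and every planted
locus is recorded in a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._pairwise import revcomp
from .io_formats import Candidate, TELibraryEntry, write_fasta

__all__ = [
    "TEDefinition",
    "Planting",
    "HairpinDefinition",
    "SyntheticSpec",
    "PlantedLocus",
    "GenomeFixture",
    "generate_genome",
    "make_candidate",
    "default_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TEDefinition:
    name: str
    length: int = 100
    te_class: str = "DNA/Mariner"


@dataclass(frozen=True)
class Planting:
    te_name: str
    n_copies: int
    mutation_rate: float = 0.05
    chromosomes: tuple[str, ...] | None = None  # None = spread over all


@dataclass(frozen=True)
class HairpinDefinition:
    """A unique hairpin locus: stem + loop + reverse-complemented stem.

    The default geometry (30-nt stems, 40-nt loop) keeps the minus-strand
    self-match of the palindromic stems below the similar-hit identity
    threshold, so a unique hairpin yields exactly one similar hit.
    """

    name: str
    stem_len: int = 30
    loop_len: int = 40


@dataclass
class SyntheticSpec:
    """Recipe for a reproducible synthetic genome."""

    n_chromosomes: int = 3
    chromosome_lengths: tuple[int, ...] = (100_000, 100_000, 100_000)
    te_definitions: tuple[TEDefinition, ...] = ()
    plantings: tuple[Planting, ...] = ()
    unique_hairpins: tuple[HairpinDefinition, ...] = ()
    seed: int = 0
    # planting keeps away from chromosome ends unless flank clipping is under test
    edge_margin: int = 200

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must match n_chromosomes")
        if any(l < 1000 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be >= 1 kb")


@dataclass(frozen=True)
class PlantedLocus:
    name: str
    chromosome: str
    start: int
    end: int
    strand: str
    identity_pct: float


@dataclass
class GenomeFixture:
    """A generated genome with its masters and ground-truth planting table."""

    spec: SyntheticSpec
    records: dict[str, str]
    te_masters: dict[str, TELibraryEntry]
    hairpin_masters: dict[str, str]
    truth: list[PlantedLocus] = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": t.name,
                    "chromosome": t.chromosome,
                    "start": t.start,
                    "end": t.end,
                    "strand": t.strand,
                    "identity_pct": round(t.identity_pct, 2),
                }
                for t in self.truth
            ],
            columns=["name", "chromosome", "start", "end", "strand", "identity_pct"],
        )

    def te_library(self) -> list[TELibraryEntry]:
        return list(self.te_masters.values())

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "genome.fa")
        write_fasta(self.te_library(), outdir / "te_library.fa")
        self.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, float]:
    """Per-base substitution at the given rate; returns (sequence, identity%)."""
    if rate <= 0:
        return seq, 100.0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    n_mut = 0
    for i in np.nonzero(hit)[0]:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
        n_mut += 1
    return arr.tobytes().decode(), 100.0 * (len(arr) - n_mut) / len(arr)


def _make_hairpin(rng: np.random.Generator, stem_len: int, loop_len: int) -> str:
    stem = _random_seq(rng, stem_len)
    loop = _random_seq(rng, loop_len)
    return stem + loop + revcomp(stem)


def generate_genome(spec: SyntheticSpec) -> GenomeFixture:
    """Generate background chromosomes and overwrite them with planted copies
    at non-overlapping recorded positions on random strands."""
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    backgrounds = {name: _random_seq(rng, l) for name, l in zip(chrom_names, spec.chromosome_lengths)}

    te_masters = {
        d.name: TELibraryEntry(d.name, _random_seq(rng, d.length), te_class=d.te_class)
        for d in spec.te_definitions
    }
    hairpin_masters = {
        h.name: _make_hairpin(rng, h.stem_len, h.loop_len) for h in spec.unique_hairpins
    }

    arrays = {name: np.frombuffer(seq.encode(), dtype="S1").copy() for name, seq in backgrounds.items()}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_names}
    truth: list[PlantedLocus] = []

    def plant(name: str, master: str, chroms: list[str], mutation_rate: float) -> None:
        chrom = chroms[len(truth) % len(chroms)]
        arr = arrays[chrom]
        lo, hi = spec.edge_margin, len(arr) - spec.edge_margin - len(master)
        if hi <= lo:
            raise ValueError(f"chromosome {chrom} too short to plant {name}")
        for _ in range(200):
            start = int(rng.integers(lo, hi))
            end = start + len(master)
            if all(end <= s or start >= e for s, e in occupied[chrom]):
                break
        else:
            raise ValueError(f"no space left to plant {name} on {chrom}")
        mutated, identity = _mutate(rng, master, mutation_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = mutated if strand == "+" else revcomp(mutated)
        arr[start:end] = np.frombuffer(inserted.encode(), dtype="S1")
        occupied[chrom].append((start, end))
        truth.append(PlantedLocus(name, chrom, start, end, strand, identity))

    for planting in spec.plantings:
        master = te_masters[planting.te_name].sequence
        chroms = list(planting.chromosomes) if planting.chromosomes else chrom_names
        for _ in range(planting.n_copies):
            plant(planting.te_name, master, chroms, planting.mutation_rate)
    for hname, hseq in hairpin_masters.items():
        plant(hname, hseq, chrom_names, 0.0)

    records = {name: arr.tobytes().decode() for name, arr in arrays.items()}
    return GenomeFixture(
        spec=spec,
        records=records,
        te_masters=te_masters,
        hairpin_masters=hairpin_masters,
        truth=truth,
    )


def make_candidate(
    kind: str,
    fixture: GenomeFixture,
    name: str | None = None,
    te_name: str | None = None,
    hairpin_name: str | None = None,
    te_segment_nt: int = 60,
    unique_tail_nt: int = 40,
    mutation_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[Candidate, str]:
    """Build a candidate of known truth category from a generated fixture.

    Returns (candidate, truth_label). ``te`` candidates copy a planted TE
    master (optionally mutated); ``bona_fide`` candidates are planted unique
    hairpins; ``te_derived`` candidates concatenate a TE segment with a unique
    tail at least the size of a mature small RNA.
    """
    if kind not in {"bona_fide", "te", "te_derived"}:
        raise ValueError(f"unknown candidate kind {kind!r}")
    rng = rng or np.random.default_rng(fixture.spec.seed + 1)
    if kind == "bona_fide":
        hairpin_name = hairpin_name or next(iter(fixture.hairpin_masters))
        seq = fixture.hairpin_masters[hairpin_name]
        return Candidate(name or hairpin_name, seq), "BONA_FIDE"
    te_name = te_name or next(iter(fixture.te_masters))
    master = fixture.te_masters[te_name].sequence
    if kind == "te":
        seq, _ = _mutate(rng, master, mutation_rate)
        return Candidate(name or f"{te_name}_copy", seq), "TE"
    segment, _ = _mutate(rng, master[:te_segment_nt], mutation_rate)
    tail = _random_seq(rng, unique_tail_nt)
    return Candidate(name or f"{te_name}_derived", segment + tail), "TE_DERIVED"


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The standard study conditions: three 100-kb chromosomes, one 100-nt TE
    family planted 25 times at 95% identity, and ten unique hairpin loci."""
    return SyntheticSpec(
        n_chromosomes=3,
        chromosome_lengths=(100_000, 100_000, 100_000),
        te_definitions=(TEDefinition("TE1", 100, "DNA/Mariner"),),
        plantings=(Planting("TE1", 25, 0.05),),
        unique_hairpins=tuple(HairpinDefinition(f"hairpin{i + 1}") for i in range(10)),
        seed=seed,
    )
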