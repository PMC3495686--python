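# Methods

## The problem

Short non-autonomous transposable elements (MITEs, SINEs such as *Alu*) have
the same size range and hairpin-forming secondary structure as the precursors
of small non-coding RNAs (pre-miRNAs in particular). As a consequence,
small-RNA registries accumulate entries that are in fact transposable
elements, and evolutionary analyses of miRNA families inherit those
mis-annotations. `teclassifier` sorts hairpin precursor candidates into three
categories from two kinds of evidence: how the candidate's occurrences are
repeated and dispersed across the genome, and how much of its sequence is
recognizable transposable-element (TE) sequence.

* **BONA_FIDE** — essentially unique in the genome, no recognizable TE.
* **TE_DERIVED** — partially TE (a TE-free segment at least the size of a
  mature small RNA remains), or repeated/dispersed beyond the copy-number or
  chromosome thresholds without recognizable TE sequence.
* **TE** — mis-annotated: the sequence is essentially all TE; no TE-free
  segment of mature-RNA size remains.

## Pipeline

For each candidate, in order:

1. **Genomic search** (`hit_search`). Exact k-mer seeds (default k = 11) on
   both strands, chained by diagonal, each chained region resolved by a full
   local alignment of the candidate against the surrounding genomic window.
   Identity is defined as 100·matches / alignment-columns (gaps count as
   columns). Hits that align fewer than half the candidate's bases are
   discarded; overlapping hits at one locus are deduplicated keeping the best
   score regardless of strand, because one genomic interval is one occurrence
   (a hairpin-shaped candidate otherwise always matches its own locus on both
   strands, the stems being mutually reverse-complementary).
2. **Similar-hit filter.** A hit is *similar* when its identity is ≥ 80% and
   its genomic span lies between 80% and 120% of the candidate length, all
   bounds inclusive.
3. **Summary statistics.** Number of hits, similar hits, chromosomes bearing
   similar hits, and clusters. Two similar hits share a cluster iff they are
   on the same chromosome and separated by less than 100,000 nt (gap measured
   end-of-left to start-of-right, overlap counting as zero), closed
   transitively; a separation of exactly 100,000 nt splits.
4. **Consensus construction** (`consensus_builder`). The ten best similar
   hits by score (ties by chromosome, then start) are extended by 100 nt of
   genomic flank on each side (clipped at record ends; minus-strand hits
   reverse-complemented so flanks stay 5′/3′ of the occurrence). The extended
   occurrences are aligned with a progressive multiple aligner: all-pairs
   edit distances (edlib) → UPGMA guide tree → profile–profile merges under
   affine gap scoring (match +2, mismatch −1, gap open −5, extend −1).
   The consensus emits, per column, the most frequent nucleotide when its
   count reaches min(5, rows) and `N` otherwise; columns where the gap symbol
   strictly outnumbers every nucleotide are deleted so the consensus stays a
   plausible genomic sequence. Ties at the threshold break alphabetically.
   With one similar hit the "consensus" is that hit's extended sequence; with
   none it is the bare candidate.
5. **TE scan** (`te_annotation`). The consensus *and* the raw candidate are
   scanned against the TE library by local alignment of every entry in both
   orientations. After a qualifying fragment is found its span is masked with
   `N` and the entry realigned, so multiple fragments of one element can be
   reported. Fragments found on the consensus are transported into candidate
   coordinates through a local anchor alignment of the candidate to the
   consensus (fragments wholly in flank regions are dropped, partial overlaps
   clipped); when the candidate fails to anchor (identity < 50% or fewer than
   half its bases aligned) only the direct candidate scan contributes.
   External repeat annotations (RepeatMasker `.out` or BED), when provided
   together with candidate coordinates, are intersected with the candidate's
   region and added as `annotation`-source fragments. Coverage is computed on
   the union of all fragments; the single greatest fragment is reported
   separately.
6. **Classification** (`classifier`). Five rules, evaluated so that TE
   evidence outranks repetition evidence, exactly one firing:
   R5 fragments present and longest TE-free run < 24 nt → TE;
   R4 fragments present and longest TE-free run ≥ 24 nt → TE_DERIVED;
   R2 no fragment, ≥ 20 similar hits → TE_DERIVED;
   R3 no fragment, similar hits on ≥ 6 chromosomes → TE_DERIVED;
   R1 otherwise → BONA_FIDE.

## Parameters

| name | default | unit | role |
|---|---|---|---|
| `min_identity_pct` | 80 | % | similar-hit identity floor |
| `size_lo_pct`, `size_hi_pct` | 80, 120 | % of candidate length | similar-hit span window |
| `min_similar_hits` | 20 | hits | repetition rule (R2) |
| `min_chromosomes` | 6 | chromosomes | dispersion rule (R3) |
| `flank_nt` | 100 | nt | genomic flank per side before alignment (0 disables) |
| `top_n_hits` | 10 | hits | occurrences used for the consensus |
| `consensus_min_count` | 5 | rows | per-column emission threshold |
| `te_free_min_nt` | 24 | nt | mature-RNA size separating TE_DERIVED from TE |
| `cluster_min_separation_nt` | 100,000 | nt | cluster separation |

All are inclusive, strictly positive (`flank_nt` may be zero) and overridable
via a flat-key YAML file or keyword overrides. The repetition and dispersion
thresholds are written as inclusive ("at least 20", "six or more"); the rule
list is authoritative where prose alternates between inclusive and exclusive
phrasings.

## Alignment scoring choices

Three scoring regimes are used deliberately:

* **Multiple alignment** (step 4): match +2, mismatch −1, gap open −5,
  extend −1 — standard soft DNA scoring, appropriate because the aligned
  occurrences are already known to be homologous.
* **Hit extension and consensus anchoring**: match +2, mismatch −3, gap open
  −8, extend −3. The expected per-column score turns negative below ~60%
  identity, so a hit's span reflects the genuinely homologous region rather
  than chance matches in its surroundings, and the anchor cannot gap-skip
  through unrelated tails.
* **Library scan** (step 5): match +2, mismatch −2, gap open −6, extend −4,
  with acceptance thresholds identity ≥ 60%, span ≥ 20 nt and score ≥ 40.
  Under this scoring the best local alignment between unrelated sequences of
  the relevant sizes (~100–300 nt) empirically stays below a score of ~30,
  while genuine fragments clear 40 comfortably (≥ 50 nt at 70% identity, or
  ≥ 20 nt near-perfect). The score floor is what excludes chance matches:
  span/identity thresholds alone admit spurious 20–40 nt alignments at
  60–75% identity between random sequences roughly 20% of the time per
  library entry. The detection limit this implies — fragments shorter than
  ~20 nt, or 24 nt below ~90% identity, are not reported — is the price of a
  clean background.

An N scores as a mismatch against everything, including itself, so an N can
never contribute a match; masking a found fragment with N therefore prevents
re-finding it without hiding the rest of the sequence.

## Read-profile analysis

Independently of the pipeline, `read_profile` computes, per candidate, the
*predominance ratio*: the count of the most frequent 5′ read start divided by
the total read count — an indicator of clean nuclease processing, not of
expression. Two groups of candidates are compared by binning their ratios
into 10 equal-width bins on (0, 1], pooling adjacent bins whose expected
counts fall below 5 (the standard chi-square validity guard), and computing
the two-sample chi-square statistic with expected counts from the pooled
proportions. The decision constant is computed, not hard-coded: the 5%
upper-tail quantile at df = bins − 1, which is 16.919 for the default 10
bins.

## Synthetic data: what it emulates and what it does not

`synthetic_data` generates i.i.d. uniform-ACGT chromosomes carrying (a)
copies of TE master sequences mutated by per-base substitution at a set rate,
planted at non-overlapping random positions on random strands, away from the
first/last 200 nt of each chromosome, and (b) unique hairpin loci
(stem + loop + reverse-complemented stem; default 30/40/30 nt, a geometry
that keeps the minus-strand self-match of the stems below the similar-hit
threshold). Every planting is recorded in a ground-truth table. Candidates
of the three categories are built from the same masters: `te` = a copy of a
planted master, `te_derived` = a TE segment plus a unique tail ≥ 24 nt,
`bona_fide` = a unique hairpin.

The standard study conditions used by the tests are three 100-kb chromosomes
with one 100-nt TE family planted 25 times at 95% identity, ten unique
hairpins, and ten candidates per category; this keeps the full suite at a few
seconds on one CPU while exercising every pipeline path (multi-hit consensus,
single-hit fallback, no-hit direct scan).

What the generator does *not* emulate: genome-scale composition bias and
repeat families of real genomes, indel mutation by default (separately
configurable in principle; substitutions keep identity arithmetic auditable),
nested/fragmented TE insertions, tandem repeats and microsatellites, and
secondary-structure-aware hairpin sequences. Passing the synthetic recovery
tests therefore demonstrates the pipeline's internal correctness and
threshold behavior, not its error rate on real genomes, where diverged and
fragmented repeats make both search and scan harder.

A residual, irreducible error mode is visible even on synthetic data: when
the random unique tail of a `te_derived` candidate happens to align to the
TE master above the scan thresholds, coverage legitimately exceeds the truth
construction and the candidate is called TE. This is a property of the
evidence, not a bug; it affects roughly one candidate in thirty under the
standard conditions.

## Degenerate inputs and tie-breaks

* Duplicate FASTA names, empty files, non-IUPAC characters: errors naming
  the offending record. `U` is normalized to `T`; ambiguity codes other than
  `N` collapse to `N`.
* Candidate shorter than the seed length: per-candidate error (batch mode
  records it and continues).
* Consensus ties at the emission threshold break alphabetically (A<C<G<T);
  top-hit score ties break by (chromosome, start); the greatest-fragment tie
  prefers scan over annotation, then smaller start.
* Coordinates are 0-based half-open internally; reports and the `region=`
  FASTA header tag use 1-based inclusive display coordinates.

## Known limitations

* The genomic search is a desk-scale stand-in for BLAT: exact 11-mer seeding
  loses sensitivity below ~80% identity for short candidates, which is
  adequate here because only ≥ 80%-identity hits are ever counted.
* The library scan reports, per entry and orientation, at most four
  fragments (iterative masking); fragments of the same element separated by
  little unrelated sequence may merge into one low-identity alignment when
  bridging is score-positive.
* Microsatellite and tandem-repeat detection is out of scope; such
  candidates are only recognized through an external annotation file.
* The chi-square comparison fixes df at bins − 1 even when sparse-bin
  pooling reduces the table; with heavy pooling the test is conservative.
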