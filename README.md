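# teclassifier

Classify hairpin ncRNA precursor candidates (e.g. pre-miRNAs) by their
relationship to transposable elements (TEs), entirely locally: no web
services, no external aligner binaries.

Short non-autonomous TEs — MITEs, SINEs such as *Alu* — share the size and
hairpin structure of small-RNA precursors, and miRNA registries consequently
contain entries that are really TEs. Given a candidate sequence, a reference
genome and a TE library, `teclassifier` measures how the candidate's
occurrences are repeated and dispersed in the genome and how much of its
sequence is recognizable TE, then applies five rules to call one of three
categories:

* `BONA_FIDE` — unique in the genome, no recognizable TE;
* `TE_DERIVED` — partially TE (a TE-free segment of at least 24 nt, the size
  of a mature mi/siRNA, remains), or repeated ≥ 20 times / dispersed over
  ≥ 6 chromosomes without recognizable TE;
* `TE` — mis-annotated: essentially all TE (no 24-nt TE-free segment).

The per-candidate pipeline: seed-and-extend genomic search → similar-hit
filter (identity ≥ 80%, span 80–120% of candidate length) → occurrence
summary and clustering (100,000-nt separation) → ten best hits extended by
100 nt of flank, progressively aligned, majority consensus (5-count rule) →
TE-library scan of consensus and candidate, optional merge with RepeatMasker
`.out`/BED annotations → coverage profile → classification. See
`docs/methods.md` for the full model, scoring choices and limitations.

## Worked example

Generate a synthetic fixture (three 100-kb chromosomes, one 100-nt TE family
planted 25 times at 95% identity, ten unique hairpin loci) and classify 30
candidates of known truth — ten per category:

```sh
teclassifier simulate --out demo --seed 0
teclassifier classify --candidates demo/candidates.fa --genome demo/genome.fa \
    --te-library demo/te_library.fa --out demo/report
```

The report (one row per candidate; columns abridged here) begins:

```
  candidate  n_hits  n_similar  n_chromosomes  n_clusters  coverage_pct  te_free_max_nt largest_te   category rule_fired
   hairpin1       1          1              1           1           0.0             100              BONA_FIDE         R1
   te_copy1      25         25              3           3         100.0               0        TE1          TE         R5
te_derived1      25          0              0           0          60.0              40        TE1  TE_DERIVED         R4
```

Reading the rows: `hairpin1` occurs once, carries no TE sequence → a genuine
precursor (rule R1). `te_copy1` has 25 similar hits on 3 chromosomes and its
consensus is fully covered by the library element `TE1` with no TE-free
segment → a mis-annotated TE (R5). `te_derived1` finds its TE half at 25
loci, but none count as similar hits (the shared segment is only 60% of its
length); the scan covers 60 of 100 nt, leaving a 40-nt TE-free run — enough
to host a mature small RNA → TE-derived (R4). On this fixture 29 of the 30
truth labels are recovered; the one miss is a `te_derived` candidate whose
random tail happens to align to the TE above the scan thresholds, so the
evidence honestly reads as full coverage.

The same operations are available as a library
(`run_pipeline`, `run_batch`, and the per-stage functions in
`hit_search`, `consensus`, `te_annotation`, `classifier`, `read_profile`,
`synthetic`), and `teclassifier readstats` computes 5′-start predominance
ratios with an optional two-group chi-square comparison.

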