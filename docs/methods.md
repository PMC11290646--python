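# Methods

## Coordinate model

All intervals are BED-style 0-based half-open `[start, end)`; GFF input
(1-based inclusive) is converted on read. Genome tiling keeps the terminal
partial bin of every chromosome, so a chromosome of length L contributes
`ceil(L / width)` bins; applied to the ce11 chromosome lengths at 200 bp
this yields 501,436 bins, which the test suite asserts.

Read-to-feature counting follows bedtools `intersect -c -wa -F 0.5` with
reads as the B file: a read counts toward a feature when at least the given
fraction of the *read* overlaps it (ties at exactly the threshold count),
and a read overlapping several qualifying features counts in each. Strand
rules: `same` (bedtools `-s`) counts reads on the feature's strand — the
non-transcribed strand (NTS) for genes annotated on their coding strand —
and `opposite` (`-S`) counts the template / transcribed strand (TS). Bin
exclusion and annotation overlap use ≥ 1 bp (bedtools default), since the
fraction rule applies only to read counting.

## Excision geometry and the 3′-anchor convention

A dual-incision product around a TT dimer at `[d, d+2)` spans
`five_prime_nt` (default 19, with ±2 nt jitter, mode 0) upstream of the
dimer and `three_prime_nt` (default 6) downstream, so the zero-jitter
product is 19 + 2 + 6 = 27 nt. Sequencing yields 19–24-nt reads; the
generator models this as 5′-only trimming, which preserves the dimer's
offset from the 3′ end at every read length. That reconciliation — ~27-nt
products, 19–24-nt reads, and a fixed 3′ dimer offset — is a modelling
choice of this package.

Positions in the dinucleotide profile are counted as **the number of
nucleotides strictly 3′ of the dinucleotide**:

```
5'  N N N N N N N N N N N [T T] x x x x x x  3'
                           dimer  position 6
```

Under this convention the dimer's 3′ base has exactly 6 nt after it and its
5′ base 7, so a 27-nt product (and any 3′-preserving trim of it) puts the
TT maximum at position 6. The generator and the profiler share the
convention, making the geometry checks self-consistent.

## Synthetic data: what it emulates

The generator produces the *statistical structure* the analysis consumes,
not sequence-level realism. Defaults (chosen once, before any result was
inspected, to keep a full run around a minute on one CPU):

- **Genome**: six 300-kb nuclear chromosomes (chrI–chrV, chrX) plus a
  13,794-bp mitochondrial contig that exercises the chromosome filter;
  i.i.d. bases with worm-like AT richness (p(A) = p(T) = 0.32). At this
  composition TT dimers occur at ~10% of positions per strand, giving every
  gene and most short loci ample damage sites.
- **Genes**: 35 per nuclear chromosome, lognormal lengths (median ~3 kb,
  clipped to 1.2–8 kb), minimum spacing 600 bp (so the 2-kb/500-bp profile
  filter retains most of them), 90% expressed with lognormal expression.
- **ncRNA landscape**: 150 piRNA loci (28 nt) confined to a 120-kb cluster
  on chrIV; 40 eRNAs (90% bidirectional); 20 lincRNAs (30% poly(A));
  30 unannotated "novel" transcribed loci; pseudogenes, miscellaneous
  ncRNAs, and an "other" class for classification tests. Transcribed
  intergenic loci are placed ≥ 2 kb from genes and ≥ 250 bp from blacklist
  regions so their bins survive the intergenic exclusion.
- **XR-seq**: per-read mixture of a TCR component (template-strand TT of
  transcribed loci, exponential 5′→3′ weight with 500-bp decay that
  flattens over the time course via per-timepoint multipliers) and a global
  component (uniform over genome TT on both strands), plus 1% uniform
  background and 2% injected duplicates; mapping qualities mostly 21–42
  with 3% ≤ 20. Genotype presets: WT (0.6, 0.4), *csb-1* (0, 1), *xpc-1*
  (1, 0) for (TCR, global) weights.
- **RNA-seq**: negative-binomial per-gene counts shared between two strains
  (dispersion 0.08), reads restricted to poly(A) features plus a 0.2%
  uniform noise floor. **Capped RNA-seq**: short-cap reads at gene TSSs and
  eRNA loci; long-cap reads over gene bodies, lincRNAs, novel loci, and
  28-nt piRNA precursors — piRNA loci deliberately receive long-cap but no
  short-cap signal.
- **Tracks/states**: piecewise-constant bedGraph tracks with promoter
  enrichment (ATAC, DNase, H3K4me3), enhancer enrichment (H3K4me1), and
  repressed domains (H3K27me3); a 20-state segmentation built from the same
  functional paint with random background states.

### Parameter recovery by construction

The planted TCR weight p is recovered from the pooled genic TS fraction via
`TS/(TS+NTS) = p + (1−p)/2`. This identity holds only when the TCR and
global components divide their reads identically between gene territory and
the rest; the generator therefore defaults the TCR component's intergenic
share to the global component's intergenic TT share (overridable). With
that coupling the pooled estimate is exact in expectation regardless of how
expression weighting and the 5′→3′ gradient distribute reads *within* the
gene cohort.

### What passing tests do not show

The generator has no sequencing errors, no PCR-duplicate structure beyond
uniform injection, no UV dose–response, no kinetic model of repair (the
per-timepoint multipliers are free parameters that only produce ordered,
monotone-ish trends), and i.i.d. base composition rather than real sequence
context. Passing tests therefore demonstrate correctness of the *analysis*
under the stated model, not performance on real libraries.

## Analysis conventions and numerical choices

- **QC filter order** follows the summary-table convention: dedup → mapq
  (strictly > 20) → chromosome → length (19–24 inclusive). Duplicates are
  defined by identical (chrom, start, end, strand); read name and quality
  are ignored.
- **Gene QC** retains genes with ≥ 10 TT dimers on TS *or* NTS and ≥ 10
  reads total across samples; the read total uses TS+NTS counts at the
  0.5-fraction rule, the same counting used everywhere else.
- **Profile gene selection**: length strictly > 2 kb and ≥ 500 bp to the
  nearest neighbouring gene on either side, any strand or biotype — the
  filter exists to prevent TS/NTS cross-contamination, which neighbouring
  genes cause regardless of strand.
- **Metagene**: TSS window [−500, +1000) and TES window [−1000, +500) in
  transcription orientation, each in 50 equal bins (100 per gene); per-bin
  counts are RPKM-normalised by bin width and library size; genes whose
  windows leave the chromosome are dropped and counted.
- **TSS heatmaps**: TSSs deduplicated by a coordinate-order scan keeping a
  TSS iff ≥ 1 kb from the last kept one (deterministic keep-first); rows
  ranked by descending total signal; "best represented half" = top 50% of
  rows by row sum.
- **TS fraction 0/0** propagates as missing (never 0) and is excluded from
  cohort means with the exclusion count logged.
- **Intergenic universe**: bins overlapping (≥ 1 bp) gene bodies,
  strand-aware 2-kb upstream extensions (clipped at chromosome bounds), or
  blacklist intervals are removed. Bin counting is unstranded (strands
  summed); time-course repair is combined as the median over the six
  timepoints per replicate, and "non-zero" detection is evaluated on those
  combined values.
- **Classification priority** for multiply-annotated bins: piRNA >
  pseudogene > protein_coding > eRNA > lincRNA > ncRNA > other; a bin with
  no overlap is unannotated. Fractions over classes plus unannotated sum
  to 1.
- **Chromatin states**: each read goes to the state with the largest
  overlap, ties to the lower state id; reads overlapping no state are
  excluded and counted. Track scores are width-weighted means over
  overlapping bedGraph intervals (continuous scoring; peak-overlap counting
  would be an alternative). Random regions resample query widths with
  replacement and are placed uniformly over the whole genome — blacklist
  exclusion is available but off by default.
- **Trend fitting**: timepoints are encoded as ordered indices 0–5 (the
  sampling times span 5 min to 48 h, three orders of magnitude, so clock
  time would let the last interval dominate the fit; log-hour encoding can
  be passed instead). Candidate breakpoints sit at interior timepoints;
  the search over ≤ 2 breakpoints is exhaustive, each placement fitted as
  continuous piecewise-linear least squares, and the breakpoint count
  chosen by BIC (`n·log(SSE/n) + (k+2)·log n`, SSE floored at 1e−12).
  Constant series report R² = 0 with no breakpoints.
- **Permutation threshold**: each permutation applies one shared shuffle of
  the timepoint labels to all genes and records the selected model's R² per
  gene; the threshold is the requested quantile of the pooled values. Using
  the selected-model R² on both the observed and permuted sides is what
  makes the null exceedance rate match 1 − quantile. Pooling across genes
  is a design choice recorded in output metadata.
- **Clades**: genes significant in both replicates are standardised and
  clustered (correlation distance, average linkage, tree cut at 2); the
  clade whose mean profile peaks earlier is "early". Degenerate cases
  (< 2 significant genes, zero-variance profiles, single-clade cuts) are
  flagged rather than silently dropped.
- **Determinism**: the pipeline spawns one named random generator per stage
  from the global seed; a fixed config reproduces every output, and the
  config fingerprint (SHA-256 of the normalised config) is recorded in the
  run report.

## Problem sizes

Defaults were sized for interactive use: ~1.8 Mb of genome, 30k reads per
XR sample (14 samples), 50k RNA and 20–30k capped reads, 200-bp bins
(~9,000 of which ~4,000 are intergenic), 50–100 permutations for trend
thresholds. A full pipeline run takes a few seconds; the complete test
suite, including the 200-matrix permutation calibration, runs in about a
minute.

## Known limitations

- The BAM world is out of scope: mapped reads enter as BED (score column =
  mapping quality); bigWig tracks enter as bedGraph.
- The rank-sum comparison assumes exchangeable region scores under the
  null; strong spatial autocorrelation in real tracks would make the
  random-region null anticonservative.
- Early/late clade labels depend on a k = 2 tree cut; profiles with more
  than two kinetic classes will be forced into two clades.
- The permutation threshold treats genes as sharing one null; strong
  across-gene dependence in real data would change the pooled quantile's
  meaning.
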