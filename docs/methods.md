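# Methods

## Model and assumptions

`iedetect` models a homozygous internal exon deletion (IED) as a maximal
run of consecutive exons whose quality-filtered median read depth is
essentially zero while the surrounding exons of the same gene retain
normal coverage. The unit of analysis is the *union exon*: overlapping
exon records of a gene's transcripts are merged, because deletions are
genomic events scored per gene, not per isoform. All internal coordinates
are 0-based half-open; conversion happens only at the GTF reader (1-based
inclusive in) and the report writers (1-based inclusive out).

Two conditions define a call within a gene with exon depths `DP_all`
(reference `R = median(DP_all)` in the default mode):

1. candidate exon: `DP_e_i < C1/100 × R` (strict inequality; a depth
   exactly at the threshold is not a candidate);
2. flanking support: `median(DP_ē) > C2/100 × R`, where ē are the
   non-candidate exons. An empty ē (every exon a candidate) fails — a
   whole-gene dropout is not an *internal* deletion, and with runs limited
   to L−1 exons a single-exon gene can never yield a call.

Runs longer than the window limit are suppressed whole, never truncated:
truncating would move candidate exons into ē and corrupt condition 2.
Candidate state resets at every gene boundary, so no call ever spans two
genes.

### Threshold reference: gene median vs sample percentile

The reference `R` is gene-scoped by default (`gene_median_fraction`): each
exon is compared against its parent gene's median exon depth. A
sample-scoped alternative (`sample_percentile`) scores condition 1 against
the C1-th percentile and condition 2 against the C2-th percentile of all
exon depths sample-wide. The two modes differ materially for *large*
deletions: when half or more of a gene's exons are deleted, the gene
median itself collapses to 0 and the gene-scoped mode has no reference
left (such genes are skipped with a warning); the sample-scoped mode still
detects them. Deletions approaching whole-gene length (e.g. 25 of 34
exons) are therefore only reachable in `sample_percentile` mode. Neither
scoping is asserted as canonical; both are exposed via
`DetectionConfig.threshold_mode`.

### Window semantics

`max_window` bounds the longest reportable run. The default is inclusive
(run length ≤ max_window, so the default 7 reports lengths 1–7), matching
summary tables that enumerate counts per window length; a `strict_window`
flag implements the alternative "length strictly less than max_window"
reading. The effective limit is always `min(window limit, L−1)`.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `c1` | 2 (%) | candidate threshold, percent of the reference depth |
| `c2` | 10 (%) | flanking-support threshold, percent of the reference |
| `max_window` | 7 (exons) | longest reportable run |
| `min_covered_fraction` | 0.9 | capture-coverage fraction each exon needs for its gene to be callable |
| `mapq_min` / `basequal_min` | 20 / 20 | read filters; strict removal below 20, a read exactly at 20 is kept |
| `gc_bin_width` | 1 (% GC) | width of the GC bins for median correction |
| `min_bin_size` | 10 (exons) | bins smaller than this fall back to no correction (m_GC = m) |
| `workers` | 1 | whole-sample parallelism |

Raising `c1` admits shallower dropouts (more calls, more false positives);
raising `max_window` admits longer runs without affecting counts at
shorter lengths. Filter mode is auto-detected from BAM `@PG` records (any
program name containing "bwa" selects the MAPQ filter, anything else the
mean-base-quality filter) and can be overridden.

## GC median correction

Depth responds unimodally to GC content. Exon GC fractions (ambiguous
bases excluded; an all-N exon has undefined GC) are binned at 1%;
corrected depth is `raw × m / m_GC` with `m` the median of all exon raw
medians and `m_GC` the median within the exon's bin. The correction is
applied to exon *median depths*, the quantity the caller consumes
throughout (an exon read-count variant would be a straightforward
substitution but is not the default). Bins below `min_bin_size` exons, and
exons with undefined GC, are left uncorrected — per-identical-GC grouping
would make most bins singletons and the correction degenerate. The m/m_GC
ratio is scale-free, so corrected depths scale linearly with sequencing
effort, and within a bin the correction preserves depth ordering.
A residual depth–GC association can survive correction when tail GC bins
are too sparse to correct; with ~30 exons per bin it is negligible.

## Numerical choices and degenerate inputs

- Medians of even-length vectors are the mean of the two central values.
- Zero-coverage bases contribute 0 to the per-base depth vector; depth is
  computed over the full exon interval, not only its captured bases — the
  90% callability rule bounds the resulting bias.
- No maximum-depth cap; duplicate, secondary, supplementary and unmapped
  records are always excluded.
- A sample whose global median depth is 0 is rejected as uncallable.
- A gene with reference median 0 (gene-scoped mode) is skipped with a
  warning rather than treated as all-candidate.
- Capture regions are normalized (sorted, merged, abutting intervals
  joined) on read; covered-base counts are exact interval arithmetic.
- Chromosome-name dialects are reconciled via an alias map at read time; a
  BAM whose header lacks an annotation chromosome is a hard error listing
  both name sets.

## Synthetic data generator

The generator emulates a small capture-sequencing experiment: by default
100 non-overlapping genes of 3–15 exons (60–300 bp) on one toy chromosome,
a capture BED covering every exon, and single-end 75 bp reads tiling each
exon to 50× expected depth, with 20 planted homozygous runs of 1–6 exons
receiving zero reads. Options add a unimodal GC depth response (quadratic
in GC, maximal at 0.45, floored at 0.25 of background), partial capture
coverage for designated genes, and fractions of low-MAPQ or low-base-quality
reads. Exon GC targets are realized exactly (up to rounding) in the
emitted sequence. Reads are placed by stratified tiling (one read per
uniform stratum of the start window with random jitter) so per-base depth
stays within ~1 of its target rather than fluctuating by √depth;
everything derives from one integer seed and is byte-reproducible.

Planted runs are capped at ⌊(L−1)/2⌋ exons so the gene median — the
default detection reference — remains positive; longer runs would be
invisible to the gene-scoped mode by construction (see above) and can be
planted with `detectable_only=False` when exercising the sample-scoped
mode.

What the generator does *not* model — and hence what passing tests do not
demonstrate about real data: sequencing errors, mappability and alignment
artifacts, insert-size structure (reads are single-end), heterozygous
deletions, tumor-normal admixture diluting the zero-depth signal, and
capture-efficiency variation beyond the GC response. Recovery of planted
runs shows the algorithm's arithmetic is right under its own model, not
that real-exome specificity equals the synthetic false-call rate.

## Problem sizes

The shipped tests and the acceptance script run on: the 100-gene planted
fixture above (one sample), a 120-gene GC-bias fixture (~1,100 exons, so
each 1% GC bin holds enough exons to correct), a 30-gene four-sample batch
for parallelism checks, and 1,000 random depth vectors of ≤ 12 exons for
exhaustive-oracle comparison. Each fixture generates in a few seconds; the
whole suite completes in well under a minute.

## Known limitations

- Homozygous deletions only; no heterozygous calling, no amplification.
- No statistical significance or FDR attached to calls.
- No padding/flanking of capture targets is applied; padded designs should
  be reflected in the BED itself.
- Tumor purity is not modelled: residual normal-tissue reads over a
  deleted exon can mask the signal.
- GTF annotation is required; every `exon` feature row (UTR-containing or
  not) is treated identically.
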