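# Methods

## Coordinate conventions

All genomic coordinates are 0-based half-open (`[start, end)`), the BED
convention; GTF input (1-based inclusive) is converted at the file boundary
and back on write, and the conversion is an involution.  Overlap is strict
half-open overlap: touching intervals do not overlap.  The TSS is
strand-aware (`interval.start` on `+`, `interval.end − 1` on `−`) and the
TSS window `[tss − flank, tss + flank + 1)` is symmetric around the TSS base
itself.  The nuclear-receptor association window runs from `upstream` bp 5′
of the TSS through the transcription end; "gene body" here means the full
transcription unit, not exons only (an exon-level reading of the rule is a
plausible alternative; the full unit matches how the metagene analysis spans
TSS→TES and is the package default).  All windows are clipped to chromosome
bounds, and every reader validates intervals against the supplied chromosome
sizes, reporting parse errors with 1-based line numbers.

## Expression classification

Fold changes use the modified-FPKM scale `log2(FPKM + c)` with pseudocount
`c = 0.1` FPKM, which bounds the dispersion of near-zero values.  Thresholds
are uniformly strict inequalities: responsive `Δlog2 > 2.5`, impaired
`Δlog2 < −1` *within the responsive set* (impairment is undefined for genes
that did not respond), dysregulated `|Δlog2| > 1`.  Eligibility — the filter
that reduces an annotation to the analyzable set — is `FPKM ≥ 0.1` in at
least one condition; this is the simplest rule that removes never-expressed
annotations, it is configurable, and it is a stand-in rather than a claim
about how any particular published gene universe was constructed.  NaN or
negative FPKM values are validation errors, never silently dropped, because
silent drops corrupt denominators.  Reported percentages round half-up at
printed precision (1 decimal for fractions, integers for penetrance).

## Peak association and co-occupancy

Association is existence of any overlap between a peak and the gene's rule
window; a peak may associate with several genes, and peaks are not merged
first (merging cannot change an existence flag).  One canonical model per
gene id is required at ingest.  Co-occupancy is defined at the peak level:
the fraction of primary peaks with at least one secondary peak within
`max_gap` bp (default 0 = direct overlap).  A gene-level alternative can be
had by combining two `associate` calls with `cross_tabulate`.

## Chi-square enrichment

"Enrichment against the total gene set" is implemented as a 2×2
[in-group vs rest] × [in-category vs not] Pearson chi-square per category
(expected counts from the product of marginals, df = 1, upper-tail p from
`scipy.stats.chi2.sf`), with a k-category goodness-of-fit alternative
(df = k − 1) selectable; both readings of the published convention exist and
the 2×2 form is the default.  No continuity correction by default (counts at
genome scale are large) and no multiple-testing correction (raw p-values
with a `p < 0.001` convention); both are available as options.  The
relative-ratio vector (category fraction in group ÷ in universe) is emitted
for chart reproduction and equals 1 in every category when the group is the
universe — in that degenerate case the 2×2 test itself is undefined and is
reported as NaN.

## Coverage analysis

Region RPKM is `reads / (kb × millions mapped)`, with reads in partially
overlapped bins pro-rated by overlap fraction (within a bin, reads are
modeled as uniformly distributed; region counts are exact under that
per-base model and are computed from a piecewise-linear prefix sum, which
makes tabulating thousands of genes vectorizable).  Normalization divides a
per-gene RPKM table by its 75th percentile under numpy's
linear-interpolation ("type 7") percentile — the most widespread default —
and records the normalizer; it requires ≥ 4 positive values and is
idempotent.  The DRB response is `log2((plus + c)/(minus + c))` on the
normalized scale with `c = 0.1` by analogy with the expression pseudocount
(normalized RPKM can be exactly 0).  Genes are partitioned at ±0.6 with the
decreased group strict (`Δlog2 < −0.6`); the three-group scheme is the
default and arbitrary edges are supported.  Metagene profiles rescale each
gene body TSS→TES into 100 bins (strand-flipped for `−` genes) with 2 kb
flanks in 20 fixed bins; genes shorter than the bin count are skipped and
counted.  The profile's y-axis is the log2 ratio of mean per-bp density per
column to a base density, which defaults to the track's genome-wide mean
density over its binned portion (the base is a free choice; any reference
track density can be passed instead).  Anchor profiles center on narrowPeak
summits when present, else interval midpoints.

## The synthetic world

The generator is the package's test bed, not a simulator of any real
genome.  Its defaults state the world the analysis assumes:

- 3.8% of genes RA-responsive (543/14,255) with a mean induction of +3 log2;
  28% of responsive genes impaired with a mean −1.5 log2 genotype effect;
  measurement noise 0.15 log2 (lognormal).  With the baseline expression at
  log2-FPKM ~ N(3, 1.5²), pseudocount shrinkage misclassifies ≲ 1–2% of
  responsive genes at the 2.5 threshold, so recovered fractions track
  configured ones within binomial error.  These constants were fixed once
  from that closed-form analysis.
- 30% of genes Ash1l targets, 20% RAR-associated, 60% of RAR peaks
  co-occupied by an Ash1l peak (drawn independently per peak).  Genes are
  placed ≥ 50 kb apart so association windows of distinct genes cannot
  collide; target peaks are placed within ±2 kb of the TSS and RAR peaks in
  the gene body ≥ 5 kb from the TSS, so the generated labels are recovered
  *exactly* by the association rules — a placement violation is a generator
  bug, not noise.
- Coverage: K36me3 marks 20% of gene bodies (me2: 70%); unmarked genes and
  3 kb flanks sit at a uniform background density.  Marked bodies get a
  lognormal density, and the DRB+ density multiplies it by
  `2^(effect + noise)` with effect −1.0 log2 (me3, non-RAR), −0.1 (me3,
  RAR-associated) or +0.3 (me2).  Bin counts are Poisson draws — count noise
  without read-level simulation.  Restricting the mark to a minority of
  gene bodies is what makes the stated world coherent end-to-end: the 75th
  percentile of the per-gene RPKM table then falls in the stable background
  population, so the configured effects survive percentile normalization
  and the RAR-vs-rest contrast is measurable through the pipeline.  Had
  every gene carried the mark, the global loss would move the normalizer
  itself and be normalized away.
- qPCR triplicates are lognormal around configured %-input means;
  phenotype tables simulate each animal carrying each phenotype
  independently at its configured penetrance, so the "any phenotype" total
  is sub-additive, as in real litters.

Everything is seeded: per-component streams are derived by hashing
`(seed, component)` so regenerating any one component (e.g. peaks only)
reproduces exactly what the full run emits, and identical configs give
byte-identical files.

What a green test on this world does **not** establish: robustness to
overlapping genes or shared promoters (placement forbids window collisions),
to mappability or GC artifacts, to fragment-length effects, or to any
peak-caller/quantifier idiosyncrasy — alignment, peak calling and transcript
quantification are upstream of this package by design.

## Statistical conventions

The t-test is the pooled-variance two-sample Student form (Welch available
as an option; the pooled form matches the conventional unqualified
"Student's t-test").  %-input is `100 × IP / (input / input_fraction)` and
background subtraction clips at zero with the clip count reported, since
%-input is non-negative by construction.  Chi-square and t p-values come
from `scipy.stats`; the statistics themselves are closed-form and tested
against hand derivations to 1e-10.

## Pipeline

`ashkit.pipeline.run_all` takes a strictly validated YAML config (unknown
keys rejected), optionally generates the synthetic inputs, and runs
expression → association → enrichment → coverage → small-statistics with
per-stage logging of the counts that make set sizes auditable.  All inputs
and outputs are digested (SHA-256) into `manifest.json`; identical config
and seed reproduce identical output digests.  Validation of input paths
happens before any stage runs.

## Known limitations

- BAM/bigWig are out of scope; coverage enters as binned bedGraph counts.
- The enrichment layer consumes an external signature reference table; it
  does not call K4me3/K27me3 domains from coverage.
- The eligibility filter and the exact contingency structure behind the
  published convention are stated package defaults, not inferences about
  any specific upstream pipeline.
- Genome-scale published counts depend on specific read archives, aligner
  and annotation versions and are not reproducible at desk scale; the test
  suite therefore anchors on printed worked examples, closed forms, oracle
  equivalence and parameter recovery.
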