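# Methods

## The measurement model

The package treats a multi-tissue RNA-seq experiment as four tables: a
genes × samples read-count matrix with gene models, per-sample
splice-junction tables in the STAR `SJ.out.tab` dialect, an annotation of
known editable sites, and per-site pileups (total and edited read counts).
Alignment, FPKM estimation, pileup generation and the hyper-editing
realignment screen are upstream tools; this package consumes their
tabular outputs and implements the comparative statistics on top of them.

Two normalized expression units coexist deliberately:

* **reads/nt** = count / merged exonic length. Used for expressed-gene
  detection (threshold 0.01, *inclusive*: "at least") and, with a strict
  `>` comparison, for the leave-one-out analysis.
* **FPKM** = count × 10⁹ / (aligned total × length). Used for TRA calling
  (high `> 5`, low `< 0.3`, both strict) and for "expressed" in mirror
  coverage and TRA-junction host-gene checks (`> 0.3`). Externally
  computed FPKM columns are accepted verbatim; the internal formula is a
  reference implementation.

Gene length is the union of exon intervals (isoforms collapsed). This is
the only length that makes reads/nt comparable across isoform-rich genes,
since any single-isoform length would penalize genes whose reads spread
over more exonic sequence.

### TRA calling and the middle band

Values in `[0.3, 5]` make a gene neither high nor low. Such a value
disqualifies TRA status in its own tissue (not high) and blocks TRA
status in every other tissue (not low). The source definitions leave this
band implicit; we enforce it strictly because the two thresholds are
printed as strict inequalities. Raising `low_fpkm` therefore weakly
enlarges every TRA set and raising `high_fpkm` weakly shrinks it — both
monotonicities are tested.

### Leave-one-out matrix

Entry (t1, t2): hold t2 out; among genes expressed in t1 and in no other
remaining sample, the fraction also expressed in t2. The denominator
depends on t1, so the matrix is asymmetric by construction and is not
symmetrized. Entries with zero denominator, and the diagonal, are NaN
rather than 0 — an undefined ratio is information, not absence. The
analysis should run on depth-matched panels; the pipeline subsamples
every column to the smallest column total first.

### Subsampling

Read subsampling operates at the count level as a multivariate
hypergeometric draw (sampling reads without replacement collapses to
exactly this distribution at the gene level). This is an approximation of
read-level sampling only in that it cannot change which read pairs
overlap which genes; for count-table consumers the two are equivalent.

### Quartile binning

Expressed genes are ranked ascending; ties keep input order (stable
sort); when n is not divisible by 4 the lower quartiles take the extra
genes first, so bin sizes differ by at most one. The convention is
arbitrary but documented and deterministic.

### Splicing metrics

Junction identity is `(chrom, intron_start, intron_end, strand)` in
1-based inclusive intron coordinates — bit-compatible with `SJ.out.tab`.
Internally all other coordinates are 0-based half-open; conversion
happens only at format boundaries. A junction is assigned to a gene when
both flanking exonic bases lie inside the gene's span and strands are
compatible (undefined junction strands match either); among multiple
containing genes the longer span wins, then the lexicographically
smaller id. Whether one anchor may fall outside the gene is not specified
by the source material; full containment is our assumption.

"Detected" means ≥ 1 unique read; the 10-read floor applies only to the
TRA-junction definition. "Not in any other tissue" is read as zero
supporting reads in the raw junction tables (exposed as
`max_other_reads`, default 0), the stricter of the two possible readings.
The statistical test behind the two-reference coverage comparison is a
two-sided Fisher exact test on the covered/uncovered 2×2 table; the
choice of test is our assumption.

### Editing statistics

* Editing level: edited/total per site; NaN at zero coverage.
* Editing rate: sites with ≥ `min_edited` edited reads over sites with
  ≥ `min_total` covering reads, within an annotated whitelist. Defaults
  `min_total=1`, `min_edited=1`; the known-site recoding screen uses
  `min_edited=5`, and the four-way support classification uses a
  10-read coverage floor. These presets are kept separate because the
  different analyses genuinely use different floors.
* Hyper-read classifier: pass iff mismatches ≥ 5 and the A→G/T→C
  fraction ≥ 0.8. The published description of the 80 % criterion is
  garbled in its source; reading it as the dominant-mismatch fraction is
  our interpretation, and both knobs are configurable. Unique sites from
  passing reads, normalized per million aligned reads, give the
  hyper-editing density.
* Fisher exact per site, two-sided by the point-probability rule (sum of
  hypergeometric outcomes no more likely than observed, with a 1e-10
  relative tie guard). This matches scipy's convention and is verified
  against exact enumeration.
* Benjamini–Hochberg: step-up with monotonicity enforcement; NaN inputs
  propagate and are excluded from m.
* Enzyme–editing correlation: Pearson by default (the method is unstated
  in the source analyses), Spearman selectable; NaN for constant inputs.

## The synthetic generator

The generator emulates the study conditions the analyses assume: one
sample per tissue (no replicates, as in the emulated panel) plus one
mTEC-like reference. Defaults: 5 tissues, 5000 genes, half housekeeping,
40 TRA genes per tissue with mirror fraction 0.6, 30 M aligned reads per
sample, negative-binomial dispersion 0.1, 20 restricted junctions per
tissue with 40 % mirrored into the reference, 500 editing sites of which
30 % carry a nonzero editing level drawn uniformly from [0.1, 0.6] at
coverage 10 + Poisson(50), and 100 hyper-edited among 1000 reads.

Counts are drawn negative-binomially around band targets (high: FPKM
6–40, mid: 0.5–4, low: < 0.2) and then clamped into guard bands (high
≥ 5.5, mid 0.4–4.5, low ≤ 0.25), so every planted threshold relation
holds deterministically rather than in expectation — recovery tests can
demand exact equality with truth. At the default library size the FPKM
bands and the 0.01 reads/nt rule coincide (0.01 reads/nt ≡ FPKM 1/3), so
mid-band genes are "expressed" under both units. A configuration whose
library size cannot realize a band for some gene length raises an error
naming `library_size`.

Editing levels are shared across samples for each edited site; with the
default coverage floor the probability that an edited site shows zero
edited reads in a sample is ≈ 0.25 %, so per-sample editing rates
concentrate tightly on the planted site fraction. Background hyper-reads
are constructed to violate the classifier thresholds by design (fewer
than five mismatches, or an editing-consistent fraction of at most one
half), which is what makes exact classifier recovery a meaningful test.

Randomness flows from a single seeded NumPy generator per stage
(`seed`, `seed+1`, `seed+2`, `seed+3` for expression, junctions, editing
and hyper-reads), with draws in a documented order, so identical
configurations reproduce byte-identical output files.

**What the generator does not emulate:** sequencing error, batch and
library-prep effects, isoform-level abundance, correlated expression
across tissues, overlapping genes, multi-mapping reads, editing levels
that differ between samples, and the long low-expression tail of
immature mTEC populations. Passing recovery tests therefore demonstrates
the correctness of the detectors under their stated definitions, not
robustness to the noise structure of real tissue panels; the noise model
(dispersion, coverage and level distributions) is exposed as
configuration rather than fixed.

## Problem sizes

The default panel (5000 genes × 6 samples, ~130 k junction observations,
3000 pileups, 1000 reads) generates in about 3 s and the full pipeline
runs in under 5 s on one core; the brute-force oracle comparisons in the
test suite use panels of tens to hundreds of genes with ≥ 100 randomized
trials, and the Fisher enumeration covers every 2×2 table with margins up
to 25.

## Known limitations

* The leave-one-out analysis and TRA calling assume the FPKM columns (or
  aligned totals) are comparable across samples; no cross-sample
  normalization is applied beyond optional depth matching of counts.
* The hyper-editing screen classifies already-aligned mismatch records;
  recovering heavily edited reads that failed alignment requires the
  upstream transform-and-realign pipeline and is out of scope.
* `junctions_per_gene_compare` counts distinct junction keys, so two
  samples sequenced at very different depths will differ systematically;
  depth-match first.
* The two-reference Fisher comparison treats junction coverage events as
  independent across junctions of a tissue, which ignores shared host
  genes.
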