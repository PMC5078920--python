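# selfmirror

Quantify how completely a promiscuously expressing reference sample — a
medullary thymic epithelial cell (mTEC) population — mirrors the
self-antigen repertoire of a panel of peripheral tissues, from bulk
RNA-seq count, splice-junction and editing-pileup tables.

mTECs tolerize developing T cells by expressing, and presenting, a large
fraction of the body's tissue-restricted antigens (TRAs). Beyond whole-gene
expression, the presented repertoire is expanded by co- and
post-transcriptional processing: alternative splicing and A-to-I / C-to-U
RNA editing. This package implements the corresponding measurements at all
three levels, plus a synthetic multi-tissue generator with planted ground
truth so every detector can be validated against known answers.

## What it computes

**Expression breadth.** A gene is *expressed* in a sample when its read
count divided by its merged exonic length is at least 0.01 reads/nt.
Per-sample expressed-gene counts (and their percentage of the gene
universe), depth-matched by multivariate-hypergeometric subsampling of the
count columns, with expression quartiles and classic median-of-ratios size
factors.

**TRA detection and mirroring.** A TRA gene is highly expressed
(FPKM > 5) in exactly one peripheral tissue and lowly expressed
(FPKM < 0.3) in every other, the mTEC-like reference samples excluded.
*Mirror coverage* is the fraction of each tissue's TRA genes the reference
expresses (FPKM > 0.3). The *leave-one-out matrix* generalizes this to
every sample pair: entry (t1, t2) is the fraction of genes uniquely
expressed in t1 (with t2 held out) that are also expressed in t2.

**Splicing diversity.** From STAR-style `SJ.out.tab` junction tables: a
gene is alternatively spliced when two of its detected junctions share a
donor or acceptor; AS fractions are reported by expression quartile over
expressed multi-exon genes. A *TRA junction* is supported by ≥ 10 unique
reads in one tissue, absent from every other, and sits in a gene expressed
in at least one additional tissue — a shared gene with a private isoform.
The reference's coverage of each tissue's TRA junctions is reported, with a
Fisher exact comparison between two reference populations.

**RNA editing.** Per-site editing levels (edited / total reads), the
per-sample *editing rate* (fraction of covered editable sites showing the
edited variant), read-weighted aggregate levels over a site panel,
editing–deaminase-expression correlation, per-site two-sample Fisher exact
tests with Benjamini–Hochberg FDR, and a hyper-editing screen: reads whose
mismatch profile is dominated (≥ 80 %) by A→G (plus strand) / T→C (minus
strand) with at least 5 mismatches, summarized as unique hyper-editing
sites per million aligned reads.

## Worked example

```python
from selfmirror import SyntheticConfig, generate_dataset
from selfmirror.tra import TraCallConfig, detect_tra_genes, mirror_coverage

ds = generate_dataset(SyntheticConfig(seed=1))
ref = ds.config.reference_sample  # "mTEChi"
tra = detect_tra_genes(ds.panel, TraCallConfig(excluded_samples=frozenset({ref})))
print({t: len(g) for t, g in sorted(tra.items())})
print(mirror_coverage(tra, ds.panel, ref))
```

```
{'brain': 40, 'kidney': 40, 'liver': 40, 'lung': 40, 'testis': 40}
brain     0.6
testis    0.6
liver     0.6
kidney    0.6
lung      0.6
Name: mirror_coverage, dtype: float64
```

The default synthetic panel plants 40 TRA genes per tissue and mirrors
60 % of each tissue's set into the mTEC-like reference; the detector
recovers all 200 planted genes and the coverage statistic returns the
planted fraction exactly. The same run yields a TRA-junction coverage of
0.4 per tissue (the planted junction-mirroring fraction) and a reference
editing rate of 0.313 over 399 annotated A-to-I sites, within binomial
noise of the planted edited-site fraction of 0.3.

The same analyses are available from the shell on TSV/BED/SJ.out.tab
inputs:

```sh
selfmirror synth --outdir data --seed 2
selfmirror tra detect --counts data/counts.tsv --samples data/samples.tsv --exclude mTEChi
selfmirror run --outdir results --seed 2   # full pipeline + summary.json
```

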