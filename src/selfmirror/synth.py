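"""Synthetic multi-tissue RNA-seq panel generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume: a panel
of peripheral tissues plus one promiscuously expressing "mTEC-like"
reference sample. Planted features:

* housekeeping genes highly expressed everywhere;
* per-tissue TRA genes high (FPKM > 5) in exactly one tissue, low
  (FPKM < 0.3) elsewhere, with a configurable fraction mirrored into the
  reference sample;
* broadly expressed filler genes at intermediate levels in every sample
  (they can never satisfy the TRA definition);
* constitutive splice junctions in every sample expressing a gene,
  alternative junctions in a configurable gene fraction, and per-tissue
  restricted junctions (support at or above the TRA-junction read floor in
  one tissue, absent elsewhere) with a fraction planted into the reference;
* editing-site pileups with coverage drawn from a configurable
  distribution and edited reads binomial around planted true levels;
* hyper-edited read mismatch profiles plus background reads constructed to
  violate the classifier thresholds.

Counts are drawn negative-binomially around band targets and then clamped
into the band, so every planted threshold relation holds deterministically,
not merely in expectation — recovery tests can demand exact ground truth.
All randomness flows from one seeded generator in a documented draw order,
so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .editing import EditingSite, ReadMismatchRecord, SitePileup
from .expression import ExpressionPanel, GeneModel
from .splicing import JunctionPanel, assign_junctions_to_genes, junction_key

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "SyntheticConfigError",
    "generate_expression",
    "generate_junctions",
    "generate_editing",
    "generate_hyper_reads",
    "generate_dataset",
    "TISSUE_NAMES",
]

#: Default tissue labels, mimicking a mouse multi-tissue panel.
TISSUE_NAMES = [
    "brain", "testis", "liver", "kidney", "lung",
    "colon", "skm", "spleen", "cTEC", "skinEC",
]

# FPKM bands the generator plants counts into. Margins keep clamped counts
# strictly clear of the analysis thresholds (0.3 low / 5 high).
_LOW_MAX_F = 0.25
_MID_MIN_F = 0.4
_MID_MAX_F = 4.5
_HIGH_MIN_F = 5.5
_HIGH_MAX_F = 50.0

_ZERO, _LOW, _MID, _HIGH = 0, 1, 2, 3


class SyntheticConfigError(ValueError):
    """An infeasible synthetic configuration (names the offending field)."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults describe the standard study panel."""

    n_tissues: int = 5
    n_genes: int = 5000
    frac_housekeeping: float = 0.5
    tra_per_tissue: int = 40
    mirror_fraction: float = 0.6
    library_size: int = 30_000_000
    nb_dispersion: float = 0.1
    gene_length_range: tuple[int, int] = (500, 5000)
    junctions_per_gene_range: tuple[int, int] = (1, 8)
    restricted_junctions_per_tissue: int = 20
    junction_mirror_fraction: float = 0.4
    junction_support_range: tuple[int, int] = (10, 80)
    alt_junction_fraction: float = 0.3
    n_editing_sites: int = 500
    edited_site_fraction: float = 0.3
    frac_c2u_sites: float = 0.2
    editing_level_distribution: tuple = ("uniform", 0.1, 0.6)
    coverage_distribution: tuple = ("poisson", 50, 10)
    n_hyper_reads: int = 100
    n_background_reads: int = 900
    reference_sample: str = "mTEChi"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tissues", "n_genes", "tra_per_tissue", "library_size",
                     "restricted_junctions_per_tissue", "n_editing_sites",
                     "n_hyper_reads", "n_background_reads"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be non-negative")
        for name in ("frac_housekeeping", "mirror_fraction", "junction_mirror_fraction",
                     "alt_junction_fraction", "edited_site_fraction", "frac_c2u_sites"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticConfigError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise SyntheticConfigError("nb_dispersion must be positive")
        if self.n_tissues < 2:
            raise SyntheticConfigError("n_tissues must be at least 2")
        budget = self.frac_housekeeping + self.n_tissues * self.tra_per_tissue / self.n_genes
        if budget > 1.0 + 1e-12:
            raise SyntheticConfigError(
                "frac_housekeeping plus the TRA gene budget exceeds n_genes "
                f"(frac_housekeeping={self.frac_housekeeping}, "
                f"n_tissues*tra_per_tissue={self.n_tissues * self.tra_per_tissue})"
            )
        for rng_name in ("gene_length_range", "junctions_per_gene_range",
                         "junction_support_range"):
            lo, hi = getattr(self, rng_name)
            if lo > hi or lo < 0:
                raise SyntheticConfigError(f"{rng_name} must be a non-empty range")
        if self.gene_length_range[0] < 50:
            raise SyntheticConfigError("gene_length_range minimum must be >= 50 nt")
        if self.junction_support_range[0] < 10:
            raise SyntheticConfigError(
                "junction_support_range must start at or above the TRA-junction "
                "read floor (10)"
            )

    @property
    def tissues(self) -> list[str]:
        names = list(TISSUE_NAMES)
        while len(names) < self.n_tissues:
            names.append(f"tissue{len(names) + 1}")
        return names[: self.n_tissues]

    @property
    def samples(self) -> list[str]:
        return self.tissues + [self.reference_sample]


@dataclass
class SyntheticTruth:
    """Machine-readable record of everything the generator planted."""

    tra_assignment: dict[str, set[str]] = field(default_factory=dict)
    mirrored_genes: set[str] = field(default_factory=set)
    restricted_junctions: dict[str, set[str]] = field(default_factory=dict)
    mirrored_junctions: dict[str, set[str]] = field(default_factory=dict)
    true_editing_levels: dict[tuple[str, str], float] = field(default_factory=dict)
    hyper_edited_read_ids: set[str] = field(default_factory=set)
    housekeeping_genes: set[str] = field(default_factory=set)
    broad_genes: set[str] = field(default_factory=set)

    def validate(self) -> None:
        seen: set[str] = set()
        for tissue, genes in self.tra_assignment.items():
            if seen & genes:
                raise AssertionError(f"TRA sets overlap at tissue {tissue}")
            seen |= genes
        if not self.mirrored_genes <= seen:
            raise AssertionError("mirrored_genes must be a subset of planted TRA genes")


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`generate_dataset`."""

    config: SyntheticConfig
    panel: ExpressionPanel
    junctions: JunctionPanel
    sites: list[EditingSite]
    pileups: list[SitePileup]
    hyper_reads: list[ReadMismatchRecord]
    truth: SyntheticTruth


# ----------------------------------------------------------------------
# expression


def _band_count_limits(band: int, length: int, library_size: int) -> tuple[int, int]:
    x = library_size * length / 1e9
    if band == _ZERO:
        return 0, 0
    if band == _LOW:
        return 0, max(0, math.floor(_LOW_MAX_F * x))
    if band == _MID:
        lo, hi = math.ceil(_MID_MIN_F * x), math.floor(_MID_MAX_F * x)
        if hi < lo:
            raise SyntheticConfigError(
                "library_size too small: no integer count yields an intermediate "
                f"FPKM in [{_MID_MIN_F}, {_MID_MAX_F}] for a gene of {length} nt "
                f"at library_size={library_size}"
            )
        return lo, hi
    lo = math.ceil(_HIGH_MIN_F * x)
    lo = max(lo, 1)
    hi = max(lo, math.floor(_HIGH_MAX_F * x))
    return lo, hi


def _make_gene_models(config: SyntheticConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Draw gene structures (draws 1-4: lengths, junction counts, strands,
    intron lengths) and lay genes along one synthetic chromosome per block."""
    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    jlo, jhi = config.junctions_per_gene_range
    n_juncs = rng.integers(jlo, jhi + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    n_chroms = config.n_tissues + 1
    cursors = {f"chr{c + 1}": 1000 for c in range(n_chroms)}
    models: list[GeneModel] = []
    width = len(str(n))
    for i in range(n):
        length = int(lengths[i])
        n_exons = int(n_juncs[i]) + 1
        n_exons = max(1, min(n_exons, length // 20))
        intron_lens = rng.integers(100, 501, size=n_exons - 1)
        chrom = f"chr{i % n_chroms + 1}"
        start = cursors[chrom]
        base, rem = divmod(length, n_exons)
        exons = []
        pos = start
        for e in range(n_exons):
            size = base + (1 if e < rem else 0)
            exons.append((pos, pos + size))
            if e < n_exons - 1:
                pos += size + int(intron_lens[e])
            else:
                pos += size
        cursors[chrom] = pos + 2000
        models.append(
            GeneModel(
                gene_id=f"G{i:0{width}d}",
                chrom=chrom,
                strand=str(strands[i]),
                exons=tuple(exons),
            )
        )
    return models


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionPanel, SyntheticTruth]:
    """Generate the count panel and start the truth record.

    Gene roles are assigned by index: the first ``frac_housekeeping`` block
    is housekeeping, then one TRA block per tissue, the remainder broadly
    expressed filler. The reference sample expresses every housekeeping and
    filler gene plus exactly ``ceil(mirror_fraction * tra_per_tissue)``
    randomly chosen TRA genes of each tissue (at intermediate levels, as in
    real promiscuous expression); the other TRA genes get zero counts there.
    """
    rng = np.random.default_rng(config.seed)
    models = _make_gene_models(config, rng)
    gene_ids = [m.gene_id for m in models]
    lengths = np.array([m.exonic_length for m in models])
    samples = config.samples
    tissues = config.tissues
    n, s = config.n_genes, len(samples)
    ref_col = s - 1

    n_hk = round(config.frac_housekeeping * n)
    n_tra_total = config.n_tissues * config.tra_per_tissue
    if n_hk + n_tra_total > n:
        raise SyntheticConfigError("gene budget exceeded")  # guarded in __post_init__

    truth = SyntheticTruth()
    band = np.full((n, s), _MID, dtype=np.int8)
    band[:n_hk, :] = _HIGH
    truth.housekeeping_genes = set(gene_ids[:n_hk])
    pos = n_hk
    n_mirror = math.ceil(config.mirror_fraction * config.tra_per_tissue)
    for j, tissue in enumerate(tissues):
        block = slice(pos, pos + config.tra_per_tissue)
        band[block, :] = _LOW
        band[block, j] = _HIGH
        band[block, ref_col] = _ZERO
        block_genes = gene_ids[pos : pos + config.tra_per_tissue]
        truth.tra_assignment[tissue] = set(block_genes)
        # draw 5 (per tissue): which TRA genes the reference mirrors
        mirrored = rng.choice(np.array(block_genes, dtype=object), size=n_mirror,
                              replace=False)
        truth.mirrored_genes |= set(mirrored)
        idx = {g: pos + k for k, g in enumerate(block_genes)}
        for g in mirrored:
            band[idx[g], ref_col] = _MID
        pos += config.tra_per_tissue
    truth.broad_genes = set(gene_ids[pos:])
    truth.validate()

    # draws 6-8: band target FPKMs (full matrices, row-major)
    shape = (n, s)
    f_high = 10 ** rng.uniform(math.log10(6.0), math.log10(40.0), size=shape)
    f_mid = 10 ** rng.uniform(math.log10(0.5), math.log10(4.0), size=shape)
    f_low = rng.uniform(0.0, 0.2, size=shape)
    target_f = np.zeros(shape)
    target_f[band == _HIGH] = f_high[band == _HIGH]
    target_f[band == _MID] = f_mid[band == _MID]
    target_f[band == _LOW] = f_low[band == _LOW]

    # draw 9: negative-binomial counts around the targets
    mu = target_f * config.library_size * lengths[:, None] / 1e9
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p, size=shape).astype(np.int64)

    # deterministic clamp into the planted band
    for gi in range(n):
        length = int(lengths[gi])
        for sj in range(s):
            lo, hi = _band_count_limits(int(band[gi, sj]), length, config.library_size)
            c = counts[gi, sj]
            counts[gi, sj] = min(max(c, lo), hi)

    col_sums = counts.sum(axis=0)
    if (col_sums > config.library_size).any():
        bad = samples[int(np.argmax(col_sums))]
        raise SyntheticConfigError(
            f"library_size={config.library_size} too small: generated counts in "
            f"sample {bad!r} sum to {int(col_sums.max())}"
        )

    panel = ExpressionPanel(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        gene_models={m.gene_id: m for m in models},
        aligned_reads_total=pd.Series(config.library_size, index=samples),
    )
    _check_planted_thresholds(panel, band, tissues)
    return panel, truth


def _check_planted_thresholds(panel, band, tissues) -> None:
    """Post-generation consistency check of the planted FPKM relations."""
    fpkm = panel.fpkm.to_numpy()
    if not (fpkm[band == _HIGH] > 5.0).all():
        raise RuntimeError("planted high-band gene failed FPKM > 5")
    if not (fpkm[band == _LOW] < 0.3).all():
        raise RuntimeError("planted low-band gene failed FPKM < 0.3")
    mid = fpkm[band == _MID]
    if not ((mid > 0.3) & (mid < 5.0)).all():
        raise RuntimeError("planted mid-band gene escaped (0.3, 5)")
    if not (fpkm[band == _ZERO] == 0).all():
        raise RuntimeError("planted zero gene has counts")


# ----------------------------------------------------------------------
# junctions


def generate_junctions(
    config: SyntheticConfig,
    panel: ExpressionPanel,
    truth: SyntheticTruth,
) -> JunctionPanel:
    """Generate per-sample junction tables consistent with the count panel.

    Constitutive junctions (one per intron) appear with random support in
    every sample where the gene is expressed (FPKM > 0.3). A configurable
    fraction of multi-exon genes additionally carries an alternative-donor
    junction sharing its acceptor with the first constitutive junction.
    Restricted junctions are alternative-acceptor variants planted into
    broadly expressed host genes: support drawn from
    ``junction_support_range`` in exactly one tissue, zero elsewhere; a
    ``junction_mirror_fraction`` of each tissue's set also appears in the
    reference sample with low support.
    """
    rng = np.random.default_rng(config.seed + 1)
    if panel.gene_models is None:
        raise ValueError("panel must carry gene models")
    models = panel.gene_models
    fpkm = panel.fpkm
    samples = config.samples
    ref = config.reference_sample
    slo, shi = config.junction_support_range

    rows: list[tuple] = []

    def star_coords(intron0: tuple[int, int]) -> tuple[int, int]:
        # 0-based half-open intron -> 1-based inclusive STAR coordinates
        return intron0[0] + 1, intron0[1]

    # draw A: which multi-exon genes carry an alternative junction
    gene_order = list(panel.genes)
    multi = [g for g in gene_order if models[g].n_exons >= 2]
    alt_mask = rng.random(len(multi)) < config.alt_junction_fraction
    alt_genes = {g for g, m in zip(multi, alt_mask) if m}

    # draw B: constitutive + alternative junction support per gene x sample
    for g in gene_order:
        gm = models[g]
        if gm.n_exons < 2:
            continue
        introns = [star_coords(iv) for iv in gm.introns]
        expressed_in = [smp for smp in samples if fpkm.at[g, smp] > 0.3]
        if not expressed_in:
            continue
        for smp in expressed_in:
            support = rng.integers(slo, shi + 1, size=len(introns))
            for (a, b), u in zip(introns, support):
                rows.append((gm.chrom, a, b, gm.strand, smp, int(u)))
            if g in alt_genes:
                a, b = introns[0]
                u_alt = int(rng.integers(slo, shi + 1))
                rows.append((gm.chrom, a + 7, b, gm.strand, smp, u_alt))

    # draw C: restricted junctions per tissue, hosts drawn from broadly
    # expressed genes (so the host is expressed in other tissues, as the
    # TRA-junction definition requires)
    n_restricted = config.n_tissues * config.restricted_junctions_per_tissue
    hosts_pool = sorted(g for g in truth.broad_genes | truth.housekeeping_genes
                        if models[g].n_exons >= 2)
    if n_restricted > 0:
        if len(hosts_pool) < n_restricted:
            raise SyntheticConfigError(
                "not enough multi-exon broadly expressed genes to host "
                f"{n_restricted} restricted junctions; genes with a single exon "
                "cannot carry a junction"
            )
        hosts = rng.choice(np.array(hosts_pool, dtype=object), size=n_restricted,
                           replace=False)
        n_jmirror = math.ceil(
            config.junction_mirror_fraction * config.restricted_junctions_per_tissue
        )
        k = 0
        for tissue in config.tissues:
            keys: list[str] = []
            for _ in range(config.restricted_junctions_per_tissue):
                gm = models[str(hosts[k])]
                k += 1
                a, b = star_coords(gm.introns[-1])
                a, b = a, b - 13  # alternative acceptor, unique to this host
                u = int(rng.integers(slo, shi + 1))
                rows.append((gm.chrom, a, b, gm.strand, tissue, u))
                keys.append(junction_key(gm.chrom, a, b, gm.strand))
            truth.restricted_junctions[tissue] = set(keys)
            # draw (per tissue): which restricted junctions the reference shows
            mirrored = rng.choice(np.array(keys, dtype=object),
                                  size=min(n_jmirror, len(keys)), replace=False)
            truth.mirrored_junctions[tissue] = set(mirrored)
            for key in keys:
                if key in truth.mirrored_junctions[tissue]:
                    chrom, span, strand = key.split(":")
                    a, b = (int(x) for x in span.split("-"))
                    u = int(rng.integers(1, 21))
                    rows.append((chrom, a, b, strand, ref, u))
    else:
        for tissue in config.tissues:
            truth.restricted_junctions[tissue] = set()
            truth.mirrored_junctions[tissue] = set()

    records = pd.DataFrame(
        rows, columns=["chrom", "intron_start", "intron_end", "strand", "sample",
                       "unique_reads"],
    )
    gene_of = assign_junctions_to_genes(records, models)
    return JunctionPanel(records, gene_of)


# ----------------------------------------------------------------------
# editing


def _draw_levels(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        _, lo, hi = dist
        return rng.uniform(lo, hi, size=size)
    if kind == "beta":
        _, a, b = dist
        return rng.beta(a, b, size=size)
    raise SyntheticConfigError(f"unknown editing_level_distribution {dist!r}")


def _draw_coverage(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "poisson":
        _, lam, offset = dist
        return offset + rng.poisson(lam, size=size)
    if kind == "nbinom":
        _, mean, dispersion = dist
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mean), size=size)
    raise SyntheticConfigError(f"unknown coverage_distribution {dist!r}")


def generate_editing(
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
) -> tuple[list[EditingSite], list[SitePileup], SyntheticTruth]:
    """Generate editing-site annotations and binomial per-site pileups.

    An ``edited_site_fraction`` of sites gets a nonzero true editing level
    (shared across samples); the rest stay at zero. Coverage per
    site/sample comes from ``coverage_distribution`` and edited reads are
    Binomial(coverage, level), so at deep coverage the observed editing
    rate of each sample concentrates on the planted site fraction.
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = truth if truth is not None else SyntheticTruth()
    n = config.n_editing_sites
    samples = config.samples

    positions = np.sort(rng.choice(np.arange(1, 10_000_001), size=n, replace=False))
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    is_c2u = rng.random(n) < config.frac_c2u_sites
    effects = rng.choice(
        np.array(["nonsynonymous", "synonymous", "noncoding", "stopgain"], dtype=object),
        size=n, p=[0.35, 0.25, 0.35, 0.05],
    )
    n_edited = round(config.edited_site_fraction * n)
    edited_idx = rng.choice(n, size=n_edited, replace=False)
    levels = np.zeros(n)
    levels[edited_idx] = _draw_levels(config.editing_level_distribution, n_edited, rng)

    sites = [
        EditingSite(
            chrom="chrE",
            pos=int(positions[i]),
            strand=str(strands[i]),
            ref_base="C" if is_c2u[i] else "A",
            edit_type="C2U" if is_c2u[i] else "A2I",
            effect=str(effects[i]),
        )
        for i in range(n)
    ]

    pileups: list[SitePileup] = []
    for i, site in enumerate(sites):
        coverage = _draw_coverage(config.coverage_distribution, len(samples), rng)
        for j, smp in enumerate(samples):
            cov = int(coverage[j])
            lvl = float(levels[i])
            edited = int(rng.binomial(cov, lvl)) if lvl > 0 else 0
            pileups.append(SitePileup(site.key, smp, cov, edited))
            truth.true_editing_levels[(site.key, smp)] = lvl
    return sites, pileups, truth


# ----------------------------------------------------------------------
# hyper-editing reads


def generate_hyper_reads(
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
) -> tuple[list[ReadMismatchRecord], SyntheticTruth]:
    """Emit hyper-edited reads plus background reads that cannot classify.

    Hyper reads carry 6-12 mismatches, all A→G on the plus strand or T→C
    on the minus strand. Background reads come in two flavors built to
    violate the classifier thresholds by design: too few mismatches
    (fewer than five, whatever their type) or mixed profiles whose
    editing-consistent fraction is at most one half.
    """
    rng = np.random.default_rng(config.seed + 3)
    truth = truth if truth is not None else SyntheticTruth()
    records: list[ReadMismatchRecord] = []
    read_len = 100
    other_pairs = [("C", "A"), ("G", "T"), ("T", "A"), ("A", "C")]

    for i in range(config.n_hyper_reads):
        rid = f"hyper_{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        ref, alt = ("A", "G") if strand == "+" else ("T", "C")
        m = int(rng.integers(6, 13))
        start = int(rng.integers(0, 1_000_000)) * read_len
        offs = np.sort(rng.choice(read_len, size=m, replace=False))
        mism = tuple((start + int(o), ref, alt, strand) for o in offs)
        records.append(ReadMismatchRecord(rid, read_len, mism, chrom="chrH",
                                          genome_start=start))
        truth.hyper_edited_read_ids.add(rid)

    for i in range(config.n_background_reads):
        rid = f"bg_{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, 1_000_000)) * read_len
        if i % 2 == 0:  # too few mismatches
            m = int(rng.integers(0, 5))
            offs = np.sort(rng.choice(read_len, size=m, replace=False))
            mism = []
            for o in offs:
                ref, alt = other_pairs[int(rng.integers(0, len(other_pairs)))]
                mism.append((start + int(o), ref, alt, strand))
        else:  # many mismatches, editing-consistent fraction <= 1/2
            m = int(rng.integers(6, 13))
            offs = np.sort(rng.choice(read_len, size=m, replace=False))
            n_edit = m // 2
            ref_e, alt_e = ("A", "G") if strand == "+" else ("T", "C")
            mism = []
            for k, o in enumerate(offs):
                if k < n_edit:
                    mism.append((start + int(o), ref_e, alt_e, strand))
                else:
                    ref, alt = other_pairs[k % len(other_pairs)]
                    mism.append((start + int(o), ref, alt, strand))
        records.append(ReadMismatchRecord(rid, read_len, tuple(mism), chrom="chrH",
                                          genome_start=start))
    return records, truth


# ----------------------------------------------------------------------


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run all four generators in order and return the full bundle."""
    panel, truth = generate_expression(config)
    junctions = generate_junctions(config, panel, truth)
    sites, pileups, truth = generate_editing(config, truth)
    hyper, truth = generate_hyper_reads(config, truth)
    truth.validate()
    return SyntheticDataset(
        config=config, panel=panel, junctions=junctions, sites=sites,
        pileups=pileups, hyper_reads=hyper, truth=truth,
    )
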