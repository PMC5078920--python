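"""RNA-editing quantification: site levels, rates, hyper-editing, testing.

Covers both deamination chemistries: A-to-I (read as A→G mismatches on the
annotated strand; ADAR enzymes) and C-to-U (C→T; APOBEC enzymes). Per-site
pileups carry the number of reads covering a known editable site and the
number carrying the edited base.

Key statistics:

* **editing level** — edited reads / total reads at one site;
* **editing rate** — fraction of covered editable sites at which the edited
  variant is observed at all;
* **hyper-editing density** — unique heavily edited sites per million
  aligned reads, from a per-read mismatch-profile classifier;
* per-site two-sample Fisher exact comparison with Benjamini–Hochberg FDR;
* aggregate (read-weighted) editing level over a site panel, and its
  correlation with deaminase expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EditingSite",
    "SitePileup",
    "ReadMismatchRecord",
    "editing_level",
    "site_support_class",
    "editing_rate",
    "classify_hyper_read",
    "hyper_editing_sites",
    "hyper_editing_density",
    "fisher_site_compare",
    "benjamini_hochberg",
    "aggregate_editing_level",
    "correlate_expression_editing",
]

_EDIT_TYPES = {"A2I": "A", "C2U": "C"}


@dataclass(frozen=True)
class EditingSite:
    """An annotated editable position (1-based) on a strand."""

    chrom: str
    pos: int
    strand: str
    ref_base: str
    edit_type: str  # A2I | C2U
    effect: str = "noncoding"  # nonsynonymous | synonymous | noncoding | stopgain

    def __post_init__(self) -> None:
        if self.edit_type not in _EDIT_TYPES:
            raise ValueError(f"unknown edit_type {self.edit_type!r}")
        if self.ref_base != _EDIT_TYPES[self.edit_type]:
            raise ValueError(
                f"{self.key}: edit_type {self.edit_type} requires ref base "
                f"{_EDIT_TYPES[self.edit_type]} on the annotated strand"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


@dataclass(frozen=True)
class SitePileup:
    """Coverage of one editing site in one sample."""

    site_key: str
    sample: str
    total_reads: int
    edited_reads: int

    def __post_init__(self) -> None:
        if not (0 <= self.edited_reads <= self.total_reads):
            raise ValueError(
                f"{self.site_key}/{self.sample}: need 0 <= edited <= total, "
                f"got {self.edited_reads}/{self.total_reads}"
            )


@dataclass(frozen=True)
class ReadMismatchRecord:
    """Mismatch profile of one aligned read.

    ``mismatches`` holds (position, ref_base, read_base, strand) tuples.
    Positions are genomic (0-based) when ``genome_start`` anchors the
    aligned span; with the default anchor of 0 they are read-relative
    offsets.
    """

    read_id: str
    aligned_length: int
    mismatches: tuple[tuple[int, str, str, str], ...]
    chrom: str = ""
    genome_start: int = 0

    def __post_init__(self) -> None:
        for pos, *_ in self.mismatches:
            if not self.genome_start <= pos < self.genome_start + self.aligned_length:
                raise ValueError(
                    f"{self.read_id}: mismatch position {pos} outside aligned span"
                )


# ----------------------------------------------------------------------


def editing_level(pileup: SitePileup) -> float:
    """Edited reads / total reads; NaN when the site has no coverage."""
    if pileup.total_reads == 0:
        return float("nan")
    return pileup.edited_reads / pileup.total_reads


def site_support_class(
    pileup: SitePileup, min_total: int = 10, min_edited: int = 1
) -> str:
    """Four-way support classification of a site in a sample.

    ``well_supported_edited`` / ``well_supported_unedited`` when coverage
    reaches ``min_total`` reads; ``low_support`` below that;
    ``no_coverage`` at zero reads. "Edited" means at least ``min_edited``
    edited reads (the known-site screen for recoding sites uses 5).
    """
    if pileup.total_reads == 0:
        return "no_coverage"
    if pileup.total_reads < min_total:
        return "low_support"
    if pileup.edited_reads >= min_edited:
        return "well_supported_edited"
    return "well_supported_unedited"


def editing_rate(
    pileups: Iterable[SitePileup],
    site_whitelist: Iterable[str] | None = None,
    min_total: int = 1,
    min_edited: int = 1,
) -> float:
    """Fraction of covered editable sites at which editing is observed.

    The denominator is the number of whitelisted sites covered by at least
    ``min_total`` reads in the sample; the numerator the subset with at
    least ``min_edited`` edited reads. NaN when no site is covered.
    """
    whitelist = set(site_whitelist) if site_whitelist is not None else None
    covered = 0
    edited = 0
    for p in pileups:
        if whitelist is not None and p.site_key not in whitelist:
            continue
        if p.total_reads >= min_total:
            covered += 1
            if p.edited_reads >= min_edited:
                edited += 1
    if covered == 0:
        return float("nan")
    return edited / covered


def _is_editing_mismatch(ref: str, alt: str, strand: str, edit_type: str = "A2I") -> bool:
    if edit_type == "A2I":
        plus, minus = ("A", "G"), ("T", "C")
    else:  # C2U
        plus, minus = ("C", "T"), ("G", "A")
    return (strand == "+" and (ref, alt) == plus) or (
        strand == "-" and (ref, alt) == minus
    )


def classify_hyper_read(
    record: ReadMismatchRecord,
    min_mismatches: int = 5,
    frac_a2g: float = 0.8,
) -> bool:
    """Is this read's mismatch profile dominated by A-to-I editing?

    True iff the read carries at least ``min_mismatches`` mismatches and
    the fraction that are A→G (plus strand) or T→C (minus strand) is at
    least ``frac_a2g``. Both thresholds are deliberately configurable: the
    dominant-mismatch fraction is the screen's least standardized knob.
    """
    n = len(record.mismatches)
    if n < min_mismatches:
        return False
    n_a2g = sum(
        _is_editing_mismatch(ref, alt, strand) for _, ref, alt, strand in record.mismatches
    )
    return n_a2g / n >= frac_a2g


def hyper_editing_sites(
    records: Iterable[ReadMismatchRecord],
    min_mismatches: int = 5,
    frac_a2g: float = 0.8,
) -> tuple[set[str], set[str]]:
    """Classify reads and collect unique A→G sites from the passing ones.

    Returns (passing read ids, unique site keys). A site key is
    ``chrom:pos:strand`` of an editing-consistent mismatch on a passing
    read; two reads covering the same genomic position contribute one
    site.
    """
    read_ids: set[str] = set()
    sites: set[str] = set()
    for rec in records:
        if not classify_hyper_read(rec, min_mismatches=min_mismatches, frac_a2g=frac_a2g):
            continue
        read_ids.add(rec.read_id)
        for pos, ref, alt, strand in rec.mismatches:
            if _is_editing_mismatch(ref, alt, strand):
                sites.add(f"{rec.chrom}:{pos}:{strand}")
    return read_ids, sites


def hyper_editing_density(unique_site_count: int, aligned_reads_total: int) -> float:
    """Unique hyper-editing sites per million aligned reads."""
    if aligned_reads_total <= 0:
        raise ValueError("aligned_reads_total must be positive")
    return unique_site_count * 1e6 / aligned_reads_total


def fisher_site_compare(pileup_a: SitePileup, pileup_b: SitePileup) -> float:
    """Two-sided Fisher exact p for one site between two samples.

    The 2x2 table is [[edited_a, unedited_a], [edited_b, unedited_b]].
    Two-sidedness follows the point-probability rule: the p-value sums the
    hypergeometric probabilities of all tables (at fixed margins) no more
    likely than the observed one. NaN when either pileup has no coverage.
    """
    if pileup_a.total_reads == 0 or pileup_b.total_reads == 0:
        return float("nan")
    a = pileup_a.edited_reads
    b = pileup_b.edited_reads
    n1 = pileup_a.total_reads
    n2 = pileup_b.total_reads
    k = a + b
    lo = max(0, k - n2)
    hi = min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n1 + n2, k, n1)
    p_obs = pmf[a - lo]
    # tolerance guards against ties broken by floating-point noise
    p = float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())
    return min(p, 1.0)


def benjamini_hochberg(p_values: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Step-up Benjamini–Hochberg q-values.

    NaN entries propagate as NaN and are excluded from the number of tests
    m. Output order matches input order; monotonicity is enforced from the
    largest p downward and q-values are capped at 1.
    """
    is_series = isinstance(p_values, pd.Series)
    arr = np.asarray(p_values, dtype=float)
    q = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    p = arr[mask]
    m = p.size
    if m:
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(ranked, 1.0)
        q[mask] = qv
    if is_series:
        return pd.Series(q, index=p_values.index, name="q_value")
    return q


def aggregate_editing_level(pileups: Iterable[SitePileup]) -> float:
    """Read-weighted editing level over a site panel.

    Total edited reads over all sites divided by total covering reads —
    equivalently the coverage-weighted mean of per-site levels. NaN when
    no read covers any site.
    """
    total = 0
    edited = 0
    for p in pileups:
        total += p.total_reads
        edited += p.edited_reads
    if total == 0:
        return float("nan")
    return edited / total


def correlate_expression_editing(
    values_x: Sequence[float],
    values_y: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between enzyme expression and editing level per sample.

    ``values_x`` are normalized deaminase read counts (e.g. median-of-ratios
    normalized), ``values_y`` matching aggregate editing levels. Pearson by
    default; ``method="spearman"`` selectable. Requires at least three
    paired samples; returns (NaN, NaN) when either vector is constant.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
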