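"""Splice-junction diversity metrics from STAR-style junction tables.

Junctions are identified by their intron coordinates in the ``SJ.out.tab``
convention: 1-based, inclusive, intron-only. The junction key is
``chrom:intron_start-intron_end:strand``. A gene is alternatively spliced
(AS) in a sample when two of its detected junctions share a donor or an
acceptor position.

Tissue-restricted (TRA) junctions capture splicing isoforms private to one
tissue: supported by at least ``support`` unique reads there, absent
(``max_other_reads`` default 0) from every other peripheral tissue, and
sitting inside a gene that is itself expressed in at least one additional
peripheral tissue — i.e. the gene is shared, the isoform is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionPanel, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "SpliceJunction",
    "JunctionPanel",
    "junction_key",
    "assign_junctions_to_genes",
    "detect_as_genes",
    "as_fraction_by_quartile",
    "junctions_per_gene_compare",
    "detect_tra_junctions",
    "tra_junction_coverage",
    "compare_coverage_two_references",
]


@dataclass(frozen=True)
class SpliceJunction:
    """One junction observation in one sample (STAR dialect coordinates)."""

    chrom: str
    intron_start: int  # 1-based, inclusive (first intronic base)
    intron_end: int  # 1-based, inclusive (last intronic base)
    strand: str  # '+', '-' or '.' (undefined)
    unique_reads: int

    def __post_init__(self) -> None:
        if not self.intron_start < self.intron_end:
            raise ValueError(
                f"intron_start must precede intron_end "
                f"({self.chrom}:{self.intron_start}-{self.intron_end})"
            )
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be non-negative")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> str:
        return junction_key(self.chrom, self.intron_start, self.intron_end, self.strand)


def junction_key(chrom: str, intron_start: int, intron_end: int, strand: str) -> str:
    return f"{chrom}:{intron_start}-{intron_end}:{strand}"


class JunctionPanel:
    """Per-sample junction support plus a junction -> gene assignment.

    Stored as a tidy frame with one row per (junction, sample) observation
    (columns ``chrom, intron_start, intron_end, strand, sample,
    unique_reads``) and a mapping junction key -> gene_id (None for
    unassigned junctions, which are retained).
    """

    COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "sample", "unique_reads"]

    def __init__(self, records: pd.DataFrame, gene_of: Mapping[str, str | None]):
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"junction records missing columns {sorted(missing)}")
        records = records.copy()
        records["key"] = (
            records["chrom"].astype(str)
            + ":"
            + records["intron_start"].astype(str)
            + "-"
            + records["intron_end"].astype(str)
            + ":"
            + records["strand"].astype(str)
        )
        self.records = records
        self.gene_of = dict(gene_of)

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample"].unique())

    def support_matrix(self) -> pd.DataFrame:
        """Junction-key x sample matrix of unique-read support (0 = absent)."""
        return (
            self.records.pivot_table(
                index="key", columns="sample", values="unique_reads", aggfunc="sum", fill_value=0
            )
            .astype(int)
        )

    def junctions_in_sample(self, sample: str, min_reads: int = 1) -> pd.DataFrame:
        sub = self.records[
            (self.records["sample"] == sample) & (self.records["unique_reads"] >= min_reads)
        ]
        return sub


def assign_junctions_to_genes(
    junctions: Iterable[SpliceJunction] | pd.DataFrame,
    gene_models: Mapping[str, GeneModel],
) -> dict[str, str | None]:
    """Assign each junction key to at most one gene.

    A junction belongs to a gene when both flanking exonic bases (the bases
    immediately before intron_start and after intron_end) lie within the
    gene's genomic span and the strands are compatible (an undefined
    junction strand matches either). When several genes contain a junction
    the one with the longer span wins (it "contains" the junction with more
    context); remaining ties go to the lexicographically smaller gene id.
    Intergenic junctions map to None.
    """
    if isinstance(junctions, pd.DataFrame):
        rows = junctions[["chrom", "intron_start", "intron_end", "strand"]].drop_duplicates()
        keys = [
            (str(c), int(s), int(e), str(st))
            for c, s, e, st in rows.itertuples(index=False)
        ]
    else:
        keys = sorted(
            {(j.chrom, j.intron_start, j.intron_end, j.strand) for j in junctions}
        )
    # per chromosome: genes sorted by span start, with a running maximum of
    # span ends so the backwards scan can stop early
    by_chrom: dict[str, tuple[list[int], list[int], list[GeneModel]]] = {}
    for chrom in {gm.chrom for gm in gene_models.values()}:
        genes = sorted(
            (gm for gm in gene_models.values() if gm.chrom == chrom),
            key=lambda gm: gm.span,
        )
        starts = [gm.span[0] for gm in genes]
        prefix_max_end: list[int] = []
        cur = 0
        for gm in genes:
            cur = max(cur, gm.span[1])
            prefix_max_end.append(cur)
        by_chrom[chrom] = (starts, prefix_max_end, genes)

    from bisect import bisect_right

    out: dict[str, str | None] = {}
    for chrom, s1, e1, strand in keys:
        # flanking exonic bases in 0-based coordinates
        left0 = (s1 - 1) - 1
        right0 = e1  # base after the intron, 0-based
        best: GeneModel | None = None
        starts, prefix_max_end, genes = by_chrom.get(chrom, ([], [], []))
        i = bisect_right(starts, left0) - 1
        while i >= 0:
            if prefix_max_end[i] <= right0:
                break  # no gene at or before i can contain the junction
            gm = genes[i]
            i -= 1
            g0, g1 = gm.span
            if not (g0 <= left0 and right0 < g1):
                continue
            if strand != "." and strand != gm.strand:
                continue
            if best is None:
                best = gm
            else:
                span_b = best.span[1] - best.span[0]
                span_g = g1 - g0
                if span_g > span_b or (span_g == span_b and gm.gene_id < best.gene_id):
                    best = gm
        key = junction_key(chrom, s1, e1, strand)
        out[key] = best.gene_id if best is not None else None
        if best is None:
            logger.debug("junction %s not assigned to any gene", key)
    return out


def _gene_junction_counts(
    panel: JunctionPanel, sample: str, min_reads: int = 1
) -> dict[str, list[str]]:
    """Gene -> keys of its junctions detected in ``sample``."""
    sub = panel.junctions_in_sample(sample, min_reads=min_reads)
    out: dict[str, list[str]] = {}
    for key in sub["key"]:
        gene = panel.gene_of.get(key)
        if gene is not None:
            out.setdefault(gene, []).append(key)
    return out


def detect_as_genes(panel: JunctionPanel, sample: str, min_reads: int = 1) -> set[str]:
    """Genes alternatively spliced in ``sample``.

    A gene is flagged when two of its junctions detected in the sample
    (>= ``min_reads`` unique reads) share an intron start or an intron end.
    """
    sub = panel.junctions_in_sample(sample, min_reads=min_reads)
    genes = sub["key"].map(panel.gene_of)
    sub = sub.assign(gene=genes).dropna(subset=["gene"])
    uniq = sub.drop_duplicates(
        subset=["gene", "chrom", "intron_start", "intron_end", "strand"]
    )
    # after deduplication, two rows agreeing on (gene, chrom, start) are
    # distinct junctions sharing a start; same for ends
    shares_start = uniq.duplicated(subset=["gene", "chrom", "intron_start"], keep=False)
    shares_end = uniq.duplicated(subset=["gene", "chrom", "intron_end"], keep=False)
    return set(uniq.loc[shares_start | shares_end, "gene"].astype(str))


def as_fraction_by_quartile(
    junction_panel: JunctionPanel,
    expression_panel: ExpressionPanel,
    sample: str,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Fraction of AS genes per expression quartile (multi-exon genes only).

    The denominator in each quartile is the number of expressed multi-exon
    genes assigned to that quartile; the numerator is how many of those are
    alternatively spliced in the sample.
    """
    from .expression import expression_quartiles

    if expression_panel.gene_models is None:
        raise ValueError("as_fraction_by_quartile requires gene models (exon counts)")
    quart = expression_quartiles(expression_panel, sample)
    multi = quart.index[
        [expression_panel.gene_models[g].n_exons >= 2 for g in quart.index]
    ]
    quart = quart.loc[multi]
    as_genes = detect_as_genes(junction_panel, sample, min_reads=min_reads)
    rows = []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        genes_q = quart.index[quart == q]
        n = len(genes_q)
        n_as = sum(g in as_genes for g in genes_q)
        rows.append({"quartile": q, "n_genes": n, "n_as": n_as,
                     "fraction_as": (n_as / n) if n else np.nan})
    return pd.DataFrame(rows).set_index("quartile")


def junctions_per_gene_compare(
    panel: JunctionPanel,
    expression_panel: ExpressionPanel,
    sample_a: str,
    sample_b: str,
    big_difference: int = 5,
    min_reads: int = 1,
    expressed_reads_per_nt: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene junction counts in two samples, flagging large differences.

    Only genes expressed in both samples are compared. Returns the per-gene
    table (``n_a``, ``n_b``, ``difference``) and a partition summary:
    genes where a exceeds b by more than ``big_difference`` junctions,
    the converse, and the rest.
    """
    rpn = expression_panel.reads_per_nt
    expressed_both = rpn.index[
        (rpn[sample_a] >= expressed_reads_per_nt) & (rpn[sample_b] >= expressed_reads_per_nt)
    ]
    counts_a = {g: len(k) for g, k in _gene_junction_counts(panel, sample_a, min_reads).items()}
    counts_b = {g: len(k) for g, k in _gene_junction_counts(panel, sample_b, min_reads).items()}
    table = pd.DataFrame(
        {
            "n_a": [counts_a.get(g, 0) for g in expressed_both],
            "n_b": [counts_b.get(g, 0) for g in expressed_both],
        },
        index=expressed_both,
    )
    table["difference"] = table["n_a"] - table["n_b"]
    summary = {
        "a_exceeds_b": int((table["difference"] > big_difference).sum()),
        "b_exceeds_a": int((table["difference"] < -big_difference).sum()),
        "within": int((table["difference"].abs() <= big_difference).sum()),
    }
    return table, summary


def detect_tra_junctions(
    junction_panel: JunctionPanel,
    expression_panel: ExpressionPanel,
    support: int = 10,
    excluded_samples: Iterable[str] = (),
    expressed_fpkm: float = 0.3,
    max_other_reads: int = 0,
) -> dict[str, set[str]]:
    """Tissue-restricted junctions per tissue.

    Junction j is a TRA junction of tissue t iff its unique-read support is
    >= ``support`` in t, <= ``max_other_reads`` (default 0) in every other
    non-excluded tissue, j is assigned to a gene, and that gene is
    expressed (FPKM > ``expressed_fpkm``) in at least one non-excluded
    tissue other than t. Junctions without a gene assignment are silently
    ineligible.
    """
    excluded = set(excluded_samples)
    tissues = [s for s in expression_panel.samples if s not in excluded]
    sup = junction_panel.support_matrix().reindex(columns=tissues, fill_value=0)
    fpkm = expression_panel.fpkm[tissues]
    result: dict[str, set[str]] = {t: set() for t in tissues}
    sup_np = sup.to_numpy()
    for j, t in enumerate(tissues):
        others = [k for k in range(len(tissues)) if k != j]
        cand = (sup_np[:, j] >= support) & (sup_np[:, others] <= max_other_reads).all(axis=1)
        for key in sup.index[cand]:
            gene = junction_panel.gene_of.get(key)
            if gene is None:
                logger.debug("TRA-junction candidate %s has no gene; skipped", key)
                continue
            if gene not in fpkm.index:
                continue
            host_expr = fpkm.loc[gene].drop(t) > expressed_fpkm
            if host_expr.any():
                result[t].add(key)
    return result


def tra_junction_coverage(
    tra_junction_sets: dict[str, set[str]],
    junction_panel: JunctionPanel,
    reference_sample: str,
    min_reads: int = 1,
) -> pd.Series:
    """Fraction of each tissue's TRA junctions detected in the reference.

    Detection means >= ``min_reads`` unique reads in ``reference_sample``.
    Tissues with no TRA junctions get NaN.
    """
    sup = junction_panel.support_matrix()
    if reference_sample in sup.columns:
        ref = sup[reference_sample]
    else:
        ref = pd.Series(0, index=sup.index)
    out = {}
    for tissue, keys in tra_junction_sets.items():
        if not keys:
            out[tissue] = np.nan
            continue
        covered = sum(int(ref.get(k, 0)) >= min_reads for k in keys)
        out[tissue] = covered / len(keys)
    return pd.Series(out, name="tra_junction_coverage")


def compare_coverage_two_references(
    tra_junction_sets: dict[str, set[str]],
    junction_panel: JunctionPanel,
    ref_a: str,
    ref_b: str,
    min_reads: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-tissue Fisher exact comparison of TRA-junction coverage.

    Builds, per tissue, the 2x2 table of covered/uncovered TRA junctions in
    the two reference samples and reports the two-sided p-value; tissues
    with an empty TRA-junction set get NaN.
    """
    sup = junction_panel.support_matrix()
    rows = []
    for tissue, keys in sorted(tra_junction_sets.items()):
        if not keys:
            rows.append({"tissue": tissue, "covered_a": 0, "covered_b": 0,
                         "n_junctions": 0, "p_value": np.nan, "significant": False})
            continue
        def _cov(ref: str) -> int:
            col = sup[ref] if ref in sup.columns else pd.Series(0, index=sup.index)
            return sum(int(col.get(k, 0)) >= min_reads for k in keys)

        ca, cb = _cov(ref_a), _cov(ref_b)
        n = len(keys)
        _, p = stats.fisher_exact([[ca, n - ca], [cb, n - cb]], alternative="two-sided")
        rows.append({"tissue": tissue, "covered_a": ca, "covered_b": cb,
                     "n_junctions": n, "p_value": float(p),
                     "significant": bool(p <= alpha)})
    return pd.DataFrame(rows).set_index("tissue")
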