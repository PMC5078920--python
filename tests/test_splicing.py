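"""Junction-to-gene assignment, AS detection, per-gene junction counts,
tissue-restricted junctions and their reference coverage."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selfmirror.expression import GeneModel
from selfmirror.splicing import (
    JunctionPanel,
    SpliceJunction,
    assign_junctions_to_genes,
    compare_coverage_two_references,
    detect_as_genes,
    detect_tra_junctions,
    junction_key,
    junctions_per_gene_compare,
    tra_junction_coverage,
)
from conftest import make_panel


def records_frame(rows):
    return pd.DataFrame(rows, columns=JunctionPanel.COLUMNS)


def panel_from_rows(rows, gene_models):
    records = records_frame(rows)
    return JunctionPanel(records, assign_junctions_to_genes(records, gene_models))


class TestAssign:
    def test_junction_inside_gene(self, toy_gene_models):
        # intron of gA between exon 1 and 2: 0-based gap [200, 400)
        # -> STAR 1-based inclusive 201..400
        out = assign_junctions_to_genes(
            [SpliceJunction("chr1", 201, 400, "+", 5)], toy_gene_models
        )
        assert out["chr1:201-400:+"] == "gA"

    def test_intergenic_junction_unassigned(self, toy_gene_models):
        out = assign_junctions_to_genes(
            [SpliceJunction("chr1", 1000, 1500, "+", 5)], toy_gene_models
        )
        assert out["chr1:1000-1500:+"] is None

    def test_strand_mismatch_blocks(self, toy_gene_models):
        out = assign_junctions_to_genes(
            [SpliceJunction("chr1", 201, 400, "-", 5)], toy_gene_models
        )
        assert out["chr1:201-400:-"] is None

    def test_undefined_strand_matches_any(self, toy_gene_models):
        out = assign_junctions_to_genes(
            [SpliceJunction("chr1", 201, 400, ".", 5)], toy_gene_models
        )
        assert out["chr1:201-400:."] == "gA"

    def test_flank_outside_span_blocks(self, toy_gene_models):
        # gA span is [100, 800); an intron ending at its last base would
        # need a flanking exonic base at 800, outside the span
        out = assign_junctions_to_genes(
            [SpliceJunction("chr1", 201, 800, "+", 5)], toy_gene_models
        )
        assert out["chr1:201-800:+"] is None

    def test_overlapping_genes_tie_rule(self):
        inner = GeneModel("inner", "chr1", "+", ((0, 300), (600, 900)))
        outer = GeneModel("outer", "chr1", "+", ((0, 500), (800, 2000)))
        out = assign_junctions_to_genes(
            [SpliceJunction("chr1", 301, 600, "+", 5)],
            {"inner": inner, "outer": outer},
        )
        assert out["chr1:301-600:+"] == "outer"  # longer span wins


def brute_force_as(panel: JunctionPanel, sample: str) -> set[str]:
    """Independent pairwise comparison over each gene's junctions."""
    sub = panel.junctions_in_sample(sample)
    by_gene: dict[str, set[tuple]] = {}
    for r in sub.itertuples(index=False):
        gene = panel.gene_of.get(r.key)
        if gene is not None:
            by_gene.setdefault(gene, set()).add(
                (r.chrom, r.intron_start, r.intron_end, r.strand)
            )
    flagged = set()
    for gene, juncs in by_gene.items():
        for j1, j2 in itertools.combinations(juncs, 2):
            same_start = j1[0] == j2[0] and j1[1] == j2[1]
            same_end = j1[0] == j2[0] and j1[2] == j2[2]
            if same_start or same_end:
                flagged.add(gene)
    return flagged


class TestDetectAs:
    def test_shared_start_flags_gene(self, toy_gene_models):
        rows = [("chr1", 201, 400, "+", "s", 5), ("chr1", 201, 650, "+", "s", 5)]
        assert detect_as_genes(panel_from_rows(rows, toy_gene_models), "s") == {"gA"}

    def test_disjoint_junctions_do_not_flag(self, toy_gene_models):
        rows = [("chr1", 201, 400, "+", "s", 5), ("chr1", 501, 700, "+", "s", 5)]
        assert detect_as_genes(panel_from_rows(rows, toy_gene_models), "s") == set()

    def test_single_junction_not_as(self, toy_gene_models):
        rows = [("chr1", 201, 400, "+", "s", 5)]
        assert detect_as_genes(panel_from_rows(rows, toy_gene_models), "s") == set()

    def test_adding_junction_never_unflags(self, toy_gene_models):
        rows = [("chr1", 201, 400, "+", "s", 5), ("chr1", 201, 650, "+", "s", 5)]
        more = rows + [("chr1", 231, 400, "+", "s", 2)]
        assert {"gA"} <= detect_as_genes(panel_from_rows(more, toy_gene_models), "s")

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(12)
        # 8 genes, each with up to 6 junctions drawn from a small
        # coordinate grid so shared endpoints arise often
        models = {}
        for i in range(8):
            base = 10_000 * i
            models[f"g{i}"] = GeneModel(
                f"g{i}", "chr1", "+",
                ((base, base + 100), (base + 2000, base + 2100)),
            )
        for _ in range(25):
            rows = []
            for i in range(8):
                base = 10_000 * i
                for _ in range(rng.integers(0, 6)):
                    a = base + 101 + 10 * rng.integers(0, 4)
                    b = base + 1900 + 10 * rng.integers(0, 4)
                    rows.append(("chr1", a, b, "+", "s", int(rng.integers(1, 30))))
            panel = panel_from_rows(rows, models) if rows else None
            if panel is None:
                continue
            assert detect_as_genes(panel, "s") == brute_force_as(panel, "s")


class TestJunctionsPerGene:
    def _setup(self, toy_gene_models, n_a, n_b):
        rows = []
        for k in range(n_a):
            rows.append(("chr1", 201 + k, 400, "+", "sa", 5))
        for k in range(n_b):
            rows.append(("chr1", 201 + k, 400, "+", "sb", 5))
        panel = panel_from_rows(rows, toy_gene_models)
        expr = make_panel({"sa": [100, 100], "sb": [100, 100]}, lengths=[100, 100])
        expr.counts.index = ["gA", "gB"]
        expr.lengths.index = ["gA", "gB"]
        return panel, expr

    def test_identical_tables_within_threshold(self, toy_gene_models):
        panel, expr = self._setup(toy_gene_models, 3, 3)
        _, summary = junctions_per_gene_compare(panel, expr, "sa", "sb")
        assert summary == {"a_exceeds_b": 0, "b_exceeds_a": 0, "within": 2}

    def test_large_difference_flagged_with_direction(self, toy_gene_models):
        panel, expr = self._setup(toy_gene_models, 12, 4)
        table, summary = junctions_per_gene_compare(panel, expr, "sa", "sb")
        assert summary["a_exceeds_b"] == 1
        assert table.loc["gA", "difference"] == 8

    def test_toy_fixture_partition_matches_hand_count(self):
        rng = np.random.default_rng(13)
        models, rows = {}, []
        counts_a, counts_b = {}, {}
        for i in range(10):
            base = 100_000 * i
            models[f"g{i}"] = GeneModel(
                f"g{i}", "chr1", "+", ((base, base + 100), (base + 5000, base + 5100))
            )
            na, nb = int(rng.integers(0, 12)), int(rng.integers(0, 12))
            counts_a[f"g{i}"], counts_b[f"g{i}"] = na, nb
            for k in range(na):
                rows.append(("chr1", base + 101 + k, base + 5000, "+", "sa", 3))
            for k in range(nb):
                rows.append(("chr1", base + 101 + k, base + 5000, "+", "sb", 3))
        panel = panel_from_rows(rows, models)
        expr = make_panel({"sa": [100] * 10, "sb": [100] * 10}, lengths=[100] * 10)
        expr.counts.index = list(models)
        expr.lengths.index = list(models)
        _, summary = junctions_per_gene_compare(panel, expr, "sa", "sb")
        hand = {"a_exceeds_b": 0, "b_exceeds_a": 0, "within": 0}
        for g in models:
            d = counts_a[g] - counts_b[g]
            hand["a_exceeds_b" if d > 5 else "b_exceeds_a" if d < -5 else "within"] += 1
        assert summary == hand


def tra_junction_fixture(support_colon=10, support_lung=0, host_expr=None):
    """One junction in a host gene; configurable support and host FPKM."""
    gm = GeneModel("host", "chr1", "+", ((0, 200), (1000, 1200)))
    rows = []
    if support_colon:
        rows.append(("chr1", 201, 1000, "+", "colon", support_colon))
    if support_lung:
        rows.append(("chr1", 201, 1000, "+", "lung", support_lung))
    panel = panel_from_rows(rows, {"host": gm})
    host_expr = host_expr or {"colon": 600, "lung": 0, "liver": 600}
    expr = make_panel(
        {s: [c] for s, c in host_expr.items()}, lengths=[400],
        aligned_totals={s: 1_000_000 for s in host_expr},
    )
    expr.counts.index = ["host"]
    expr.lengths.index = ["host"]
    return panel, expr


class TestTraJunctions:
    KEY = junction_key("chr1", 201, 1000, "+")

    def test_restricted_junction_detected(self):
        panel, expr = tra_junction_fixture()
        out = detect_tra_junctions(panel, expr)
        assert out["colon"] == {self.KEY}

    def test_below_support_floor(self):
        panel, expr = tra_junction_fixture(support_colon=9)
        out = detect_tra_junctions(panel, expr)
        assert out["colon"] == set()

    def test_single_read_elsewhere_disqualifies(self):
        panel, expr = tra_junction_fixture(support_lung=1)
        out = detect_tra_junctions(panel, expr)
        assert out["colon"] == set()

    def test_host_must_be_expressed_elsewhere(self):
        panel, expr = tra_junction_fixture(host_expr={"colon": 600, "lung": 0,
                                                      "liver": 0})
        out = detect_tra_junctions(panel, expr)
        assert out["colon"] == set()

    def test_reference_reads_do_not_disqualify(self):
        gm = GeneModel("host", "chr1", "+", ((0, 200), (1000, 1200)))
        rows = [("chr1", 201, 1000, "+", "colon", 10),
                ("chr1", 201, 1000, "+", "mTEC", 50)]
        panel = panel_from_rows(rows, {"host": gm})
        expr = make_panel({"colon": [600], "liver": [600], "mTEC": [600]},
                          lengths=[400],
                          aligned_totals={s: 1_000_000 for s in ("colon", "liver", "mTEC")})
        expr.counts.index = ["host"]
        expr.lengths.index = ["host"]
        out = detect_tra_junctions(panel, expr, excluded_samples={"mTEC"})
        assert out["colon"] == {self.KEY}

    def test_sets_shrink_as_support_rises(self, small_dataset):
        ds = small_dataset
        ref = ds.config.reference_sample
        sizes = []
        for support in (10, 30, 60, 90):
            out = detect_tra_junctions(ds.junctions, ds.panel, support=support,
                                       excluded_samples={ref})
            sizes.append(sum(len(v) for v in out.values()))
        assert sizes == sorted(sizes, reverse=True)


class TestCoverage:
    def test_full_none_and_exact_fraction(self, small_dataset):
        ds = small_dataset
        ref = ds.config.reference_sample
        tra = detect_tra_junctions(ds.junctions, ds.panel, excluded_samples={ref})
        cov = tra_junction_coverage(tra, ds.junctions, ref)
        expected = ds.config.junction_mirror_fraction
        import math
        exact = math.ceil(expected * ds.config.restricted_junctions_per_tissue) \
            / ds.config.restricted_junctions_per_tissue
        assert np.allclose(cov.to_numpy(), exact)

    def test_missing_reference_sample_gives_zero(self, toy_gene_models):
        rows = [("chr1", 201, 400, "+", "colon", 10)]
        panel = panel_from_rows(rows, toy_gene_models)
        cov = tra_junction_coverage({"colon": {"chr1:201-400:+"}}, panel, "nowhere")
        assert cov.loc["colon"] == 0.0

    def test_empty_set_is_nan(self, toy_gene_models):
        rows = [("chr1", 201, 400, "+", "colon", 10)]
        panel = panel_from_rows(rows, toy_gene_models)
        assert np.isnan(tra_junction_coverage({"colon": set()}, panel, "colon")["colon"])


class TestCompareTwoReferences:
    def _panel(self, cov_a: int, cov_b: int, n: int):
        gm = GeneModel("host", "chr1", "+", ((0, 200), (100_000, 100_200)))
        rows = []
        keys = set()
        for i in range(n):
            a, b = 201 + i, 100_000
            keys.add(junction_key("chr1", a, b, "+"))
            rows.append(("chr1", a, b, "+", "colon", 10))
            if i < cov_a:
                rows.append(("chr1", a, b, "+", "refA", 3))
            if i < cov_b:
                rows.append(("chr1", a, b, "+", "refB", 3))
        return panel_from_rows(rows, {"host": gm}), {"colon": keys}

    def test_identical_coverage_p_one(self):
        panel, tra = self._panel(5, 5, 10)
        out = compare_coverage_two_references(tra, panel, "refA", "refB")
        assert out.loc["colon", "p_value"] == pytest.approx(1.0)

    def test_matches_fisher_oracle(self):
        panel, tra = self._panel(90, 50, 100)
        out = compare_coverage_two_references(tra, panel, "refA", "refB")
        _, expected = stats.fisher_exact([[90, 10], [50, 50]])
        assert out.loc["colon", "p_value"] == pytest.approx(expected, rel=1e-9)
        assert bool(out.loc["colon", "significant"])

    def test_empty_tra_set_reports_na(self, toy_gene_models):
        panel = panel_from_rows([("chr1", 201, 400, "+", "s", 1)], toy_gene_models)
        out = compare_coverage_two_references({"colon": set()}, panel, "a", "b")
        assert np.isnan(out.loc["colon", "p_value"])


def test_recovery_on_default_panel(default_dataset):
    """Detected TRA-junction sets equal the planted restricted junctions,
    and the reference covers exactly the planted fraction."""
    ds = default_dataset
    ref = ds.config.reference_sample
    tra = detect_tra_junctions(ds.junctions, ds.panel, support=10,
                               excluded_samples={ref})
    assert tra == ds.truth.restricted_junctions
    cov = tra_junction_coverage(tra, ds.junctions, ref)
    assert np.allclose(cov.to_numpy(), ds.config.junction_mirror_fraction)
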