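"""Top-level pipeline: synthesize a panel, run every analysis, emit a report.

The pipeline chains the synthetic generator through the expression, TRA,
splicing and editing analyses and collects a machine-readable summary.
Every threshold actually applied is logged, so a run leaves an audit trail
of its cut-offs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import editing as ed
from . import io as sio
from . import splicing as sp
from . import tra as tr
from .expression import (
    count_expressed_genes,
    median_of_ratios_factors,
    subsample_counts,
)
from .splicing import SpliceJunction
from .synth import SyntheticConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("synth", "expression", "tra", "splicing", "editing")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds plus the synthetic-panel settings.

    ``min_edited_rate`` (1 read) is the editing-rate preset; the
    known-site screen preset ``min_edited_screen`` (5 reads) drives the
    support-class heat-map workflow. ``subsample_depths`` lists extra read
    depths at which expressed-gene counts are recomputed.
    """

    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    expressed_reads_per_nt: float = 0.01
    high_fpkm: float = 5.0
    low_fpkm: float = 0.3
    expressed_fpkm: float = 0.3
    junction_support: int = 10
    min_total: int = 10
    min_edited_rate: int = 1
    min_edited_screen: int = 5
    fdr_alpha: float = 0.05
    subsample_depths: tuple[int, ...] = ()
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if not self.high_fpkm > self.low_fpkm >= 0:
            raise ValueError("require high_fpkm > low_fpkm >= 0")
        for name in ("expressed_reads_per_nt", "expressed_fpkm", "fdr_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("junction_support", "min_total", "min_edited_rate",
                     "min_edited_screen"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        """Build from a (YAML) mapping; unknown keys are rejected."""
        data = dict(data)
        synth_data = data.pop("synth", {})
        known_synth = {f.name for f in dataclasses.fields(SyntheticConfig)}
        bad = set(synth_data) - known_synth
        if bad:
            raise ValueError(f"unknown synth configuration keys: {sorted(bad)}")
        for key in ("gene_length_range", "junctions_per_gene_range",
                    "junction_support_range", "editing_level_distribution",
                    "coverage_distribution"):
            if key in synth_data:
                synth_data[key] = tuple(synth_data[key])
        known = {f.name for f in dataclasses.fields(cls)} - {"synth"}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown configuration keys: {sorted(bad)}")
        for key in ("subsample_depths", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(synth=SyntheticConfig(**synth_data), **data)


def _write_inputs(outdir: Path, ds: SyntheticDataset) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_counts_tsv(outdir / "counts.tsv", ds.panel.counts, ds.panel.lengths)
    sio.write_samples_tsv(outdir / "samples.tsv", ds.panel.aligned_reads_total)
    sio.write_bed12(outdir / "genes.bed", ds.panel.gene_models)
    for sample in ds.config.samples:
        sub = ds.junctions.records[ds.junctions.records["sample"] == sample]
        sub = sub.sort_values(["chrom", "intron_start", "intron_end", "strand"])
        juncs = [
            SpliceJunction(r.chrom, int(r.intron_start), int(r.intron_end),
                           r.strand, int(r.unique_reads))
            for r in sub.itertuples(index=False)
        ]
        sio.write_sj_tab(outdir / f"{sample}.SJ.out.tab", juncs)
    sio.write_sites_tsv(outdir / "editing_sites.tsv", ds.sites)
    sio.write_pileups_tsv(outdir / "pileups.tsv", ds.pileups)
    sio.write_mismatch_tsv(outdir / "hyper_reads.tsv", ds.hyper_reads)
    sio.write_truth_json(outdir / "truth.json", ds.truth)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the selected stages on a synthetic panel; return the summary.

    Deterministic given the configuration (all randomness flows from
    ``config.synth.seed``). When ``outdir`` is given, the generated input
    files, per-stage tables and ``summary.json`` are written there.
    """
    outdir = Path(outdir) if outdir is not None else None
    ds = generate_dataset(config.synth)
    ref = config.synth.reference_sample
    tissues = config.synth.tissues
    summary: dict = {"seed": config.synth.seed, "samples": config.synth.samples}

    if outdir is not None and "synth" in config.stages:
        _write_inputs(outdir, ds)

    if "expression" in config.stages:
        logger.info("expression threshold: >= %g reads/nt", config.expressed_reads_per_nt)
        expressed = count_expressed_genes(ds.panel, config.expressed_reads_per_nt)
        summary["expression"] = {
            "n_expressed": expressed["n_expressed"].to_dict(),
            "pct_of_universe": expressed["pct_of_universe"].round(4).to_dict(),
            "size_factors": median_of_ratios_factors(ds.panel.counts).round(6).to_dict(),
        }
        depths = {}
        rng = np.random.default_rng(config.synth.seed + 4)
        for depth in config.subsample_depths:
            counts = ds.panel.counts
            if any(counts[s].sum() < depth for s in counts.columns):
                logger.warning("skipping depth %d: exceeds a column total", depth)
                continue
            for sample in counts.columns:
                counts = subsample_counts(counts, sample, depth, rng)
            sub_panel = ds.panel.with_counts(counts)
            depths[str(depth)] = (
                count_expressed_genes(sub_panel, config.expressed_reads_per_nt)
                ["n_expressed"].to_dict()
            )
        if depths:
            summary["expression"]["n_expressed_at_depth"] = depths

    if "tra" in config.stages:
        logger.info("TRA thresholds: FPKM > %g high, < %g low; reference %s excluded",
                    config.high_fpkm, config.low_fpkm, ref)
        tra_cfg = tr.TraCallConfig(
            high_fpkm=config.high_fpkm, low_fpkm=config.low_fpkm,
            expressed_fpkm=config.expressed_fpkm,
            expressed_reads_per_nt=config.expressed_reads_per_nt,
            excluded_samples=frozenset({ref}),
        )
        tra_sets = tr.detect_tra_genes(ds.panel, tra_cfg)
        coverage = tr.mirror_coverage(tra_sets, ds.panel, ref, config.expressed_fpkm)
        # equal-depth panel for the leave-one-out analysis
        counts = ds.panel.counts
        floor = int(counts.sum(axis=0).min())
        rng = np.random.default_rng(config.synth.seed + 5)
        for sample in counts.columns:
            counts = subsample_counts(counts, sample, floor, rng)
        loo = tr.leave_one_out_matrix(ds.panel.with_counts(counts),
                                      config.expressed_reads_per_nt)
        off_diag = loo.to_numpy()[~np.eye(len(loo), dtype=bool)]
        summary["tra"] = {
            "n_tra_genes": {t: len(g) for t, g in sorted(tra_sets.items())},
            "mirror_coverage": coverage.round(6).to_dict(),
            "loo_reference_column_mean": float(np.nanmean(loo[ref].drop(ref))),
            "loo_offdiagonal_mean": float(np.nanmean(off_diag)),
            "loo_depth": floor,
        }
        if outdir is not None:
            loo.to_csv(outdir / "leave_one_out.tsv", sep="\t")
            rows = [(t, g) for t in sorted(tra_sets) for g in sorted(tra_sets[t])]
            pd.DataFrame(rows, columns=["tissue", "gene_id"]).to_csv(
                outdir / "tra_genes.tsv", sep="\t", index=False)

    if "splicing" in config.stages:
        logger.info("TRA-junction support floor: >= %d unique reads",
                    config.junction_support)
        as_counts = {s: len(sp.detect_as_genes(ds.junctions, s))
                     for s in config.synth.samples}
        as_quart = sp.as_fraction_by_quartile(ds.junctions, ds.panel, ref)
        tra_juncs = sp.detect_tra_junctions(
            ds.junctions, ds.panel, support=config.junction_support,
            excluded_samples={ref}, expressed_fpkm=config.expressed_fpkm,
        )
        jcov = sp.tra_junction_coverage(tra_juncs, ds.junctions, ref)
        _, jpg_summary = sp.junctions_per_gene_compare(
            ds.junctions, ds.panel, ref, tissues[0],
            expressed_reads_per_nt=config.expressed_reads_per_nt,
        )
        summary["splicing"] = {
            "n_as_genes": as_counts,
            "as_fraction_by_quartile_reference":
                as_quart["fraction_as"].round(6).to_dict(),
            "n_tra_junctions": {t: len(k) for t, k in sorted(tra_juncs.items())},
            "tra_junction_coverage": jcov.round(6).to_dict(),
            "junctions_per_gene_vs_first_tissue": jpg_summary,
        }

    if "editing" in config.stages:
        logger.info("editing rate preset: min_total=1, min_edited=%d",
                    config.min_edited_rate)
        a2i_keys = {s.key for s in ds.sites if s.edit_type == "A2I"}
        c2u_keys = {s.key for s in ds.sites if s.edit_type == "C2U"}
        by_sample: dict[str, list] = {}
        for p in ds.pileups:
            by_sample.setdefault(p.sample, []).append(p)
        rates = {
            s: ed.editing_rate(by_sample[s], a2i_keys, min_total=1,
                               min_edited=config.min_edited_rate)
            for s in config.synth.samples
        }
        c2u_levels = {
            s: ed.aggregate_editing_level(
                [p for p in by_sample[s] if p.site_key in c2u_keys])
            for s in config.synth.samples
        }
        read_ids, site_keys = ed.hyper_editing_sites(ds.hyper_reads)
        density = ed.hyper_editing_density(len(site_keys),
                                           int(ds.panel.aligned_reads_total.iloc[0]))
        ref_pile = {p.site_key: p for p in by_sample[ref]}
        n_signif = {}
        for tissue in tissues:
            pvals = []
            for p in by_sample[tissue]:
                if p.site_key not in a2i_keys:
                    continue
                pvals.append(ed.fisher_site_compare(ref_pile[p.site_key], p))
            q = ed.benjamini_hochberg(np.array(pvals))
            n_signif[tissue] = int(np.nansum(q <= config.fdr_alpha))
        summary["editing"] = {
            "editing_rate": {s: round(v, 6) for s, v in rates.items()},
            "aggregate_c2u_level": {s: round(v, 6) for s, v in c2u_levels.items()},
            "n_hyper_reads_detected": len(read_ids),
            "n_hyper_sites": len(site_keys),
            "hyper_sites_per_million_reads": round(density, 6),
            "n_sites_significant_vs_reference": n_signif,
        }

    if outdir is not None:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return summary
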