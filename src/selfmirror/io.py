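"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions at format boundaries:

* counts TSV — ``gene_id``, ``length`` and one integer column per sample;
  an optional companion samples TSV carries per-sample aligned totals.
* ``SJ.out.tab`` — the 9-column STAR dialect; intron coordinates 1-based
  inclusive; strand encoded 0/1/2 for undefined/+/-.
* editing-site TSV — BED-like with a 1-based ``pos`` column, strand, ref
  and alt bases, edit type (A2I/C2U) and coding effect.
* pileup TSV — ``site_key``, ``sample``, ``total_reads``, ``edited_reads``.
* mismatch-record TSV — one row per read with its mismatch list packed as
  ``pos:ref:alt:strand`` tokens.
* gene models — BED12 (0-based half-open blocks).

Internal coordinates are 0-based half-open everywhere; conversion happens
only in this module and in the junction containers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .editing import EditingSite, ReadMismatchRecord, SitePileup
from .expression import ExpressionPanel, GeneModel
from .splicing import SpliceJunction
from .synth import SyntheticTruth

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_samples_tsv", "write_samples_tsv",
    "read_sj_tab", "write_sj_tab",
    "read_sites_tsv", "write_sites_tsv",
    "read_pileups_tsv", "write_pileups_tsv",
    "read_mismatch_tsv", "write_mismatch_tsv",
    "read_bed12", "write_bed12",
    "read_truth_json", "write_truth_json",
    "read_config_yaml",
]

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
_CODE_STRAND = {v: k for k, v in _STRAND_CODE.items()}


class FormatError(ValueError):
    """A malformed input file; the message carries the line number."""


# ----------------------------------------------------------------------
# counts


def write_counts_tsv(path: str | Path, counts: pd.DataFrame, lengths: pd.Series) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index).astype(int))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Returns (counts genes x samples, lengths). Duplicate gene ids error."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "length"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate gene_id {df['gene_id'][dup].iloc[0]!r}"
        )
    df = df.set_index("gene_id")
    lengths = df.pop("length").astype(int)
    return df.astype(int), lengths


def write_samples_tsv(path: str | Path, aligned_reads_total: pd.Series) -> None:
    out = aligned_reads_total.rename("aligned_reads_total").to_frame()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_samples_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if df["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample label")
    return df.set_index("sample")["aligned_reads_total"].astype(int)


# ----------------------------------------------------------------------
# SJ.out.tab


def write_sj_tab(path: str | Path, junctions: Iterable[SpliceJunction]) -> None:
    """Write the 9-column STAR dialect (motif/annotated/multi set to 0)."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t"
                f"{_CODE_STRAND[j.strand]}\t0\t0\t{j.unique_reads}\t0\t30\n"
            )


def read_sj_tab(path: str | Path) -> list[SpliceJunction]:
    out: list[SpliceJunction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = _STRAND_CODE[int(fields[3])]
                unique = int(fields[6])
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                out.append(SpliceJunction(chrom, start, end, strand, unique))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


# ----------------------------------------------------------------------
# editing sites / pileups / mismatch records

_SITE_COLUMNS = ["chrom", "pos", "strand", "ref", "alt", "edit_type", "effect"]
_ALT_OF = {"A2I": {"A": "G", "T": "C"}, "C2U": {"C": "T", "G": "A"}}


def write_sites_tsv(path: str | Path, sites: Iterable[EditingSite]) -> None:
    rows = []
    for s in sites:
        alt = _ALT_OF[s.edit_type][s.ref_base]
        rows.append((s.chrom, s.pos, s.strand, s.ref_base, alt, s.edit_type, s.effect))
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> list[EditingSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    keyed = df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["strand"]
    dup = keyed.duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicate site {keyed[dup].iloc[0]!r}")
    sites = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sites.append(
                EditingSite(
                    chrom=str(row.chrom), pos=int(row.pos), strand=str(row.strand),
                    ref_base=str(row.ref), edit_type=str(row.edit_type),
                    effect=str(row.effect),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_pileups_tsv(path: str | Path, pileups: Iterable[SitePileup]) -> None:
    rows = [(p.site_key, p.sample, p.total_reads, p.edited_reads) for p in pileups]
    pd.DataFrame(
        rows, columns=["site_key", "sample", "total_reads", "edited_reads"]
    ).to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path: str | Path) -> list[SitePileup]:
    df = pd.read_csv(path, sep="\t", dtype={"site_key": str, "sample": str})
    dup = df.duplicated(subset=["site_key", "sample"])
    if dup.any():
        bad = df.loc[dup, ["site_key", "sample"]].iloc[0]
        raise FormatError(
            f"{path}: duplicate pileup for site {bad.site_key!r} / sample {bad['sample']!r}"
        )
    out = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                SitePileup(str(row.site_key), str(row.sample),
                           int(row.total_reads), int(row.edited_reads))
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_mismatch_tsv(path: str | Path, records: Iterable[ReadMismatchRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tgenome_start\taligned_length\tmismatches\n")
        for r in records:
            packed = ",".join(
                f"{pos}:{ref}:{alt}:{strand}" for pos, ref, alt, strand in r.mismatches
            )
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.genome_start}\t{r.aligned_length}\t{packed}\n")


def read_mismatch_tsv(path: str | Path) -> list[ReadMismatchRecord]:
    out: list[ReadMismatchRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "chrom", "genome_start", "aligned_length", "mismatches"]:
            raise FormatError(f"{path}:1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fields")
            rid, chrom, gstart, alen, packed = fields
            mismatches = []
            if packed:
                for token in packed.split(","):
                    try:
                        pos, ref, alt, strand = token.split(":")
                        mismatches.append((int(pos), ref, alt, strand))
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: bad mismatch token "
                                          f"{token!r}") from exc
            try:
                out.append(
                    ReadMismatchRecord(rid, int(alen), tuple(mismatches),
                                       chrom=chrom, genome_start=int(gstart))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


# ----------------------------------------------------------------------
# gene models (BED12)


def write_bed12(path: str | Path, gene_models: Mapping[str, GeneModel]) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gene_models):
            gm = gene_models[gid]
            start, end = gm.span
            sizes = ",".join(str(b - a) for a, b in gm.exons)
            starts = ",".join(str(a - start) for a, _ in gm.exons)
            fh.write(
                f"{gm.chrom}\t{start}\t{end}\t{gm.gene_id}\t0\t{gm.strand}\t"
                f"{start}\t{end}\t0\t{len(gm.exons)}\t{sizes},\t{starts},\n"
            )


def read_bed12(path: str | Path) -> dict[str, GeneModel]:
    out: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, _end, name, _score, strand = fields[:6]
            start = int(start)
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            if name in out:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(starts, sizes)
            )
            out[name] = GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons)
    return out


# ----------------------------------------------------------------------
# truth JSON / configuration


def write_truth_json(path: str | Path, truth: SyntheticTruth) -> None:
    payload = {
        "tra_assignment": {t: sorted(g) for t, g in sorted(truth.tra_assignment.items())},
        "mirrored_genes": sorted(truth.mirrored_genes),
        "restricted_junctions": {
            t: sorted(k) for t, k in sorted(truth.restricted_junctions.items())
        },
        "mirrored_junctions": {
            t: sorted(k) for t, k in sorted(truth.mirrored_junctions.items())
        },
        "true_editing_levels": {
            f"{site}|{sample}": level
            for (site, sample), level in sorted(truth.true_editing_levels.items())
        },
        "hyper_edited_read_ids": sorted(truth.hyper_edited_read_ids),
        "housekeeping_genes": sorted(truth.housekeeping_genes),
        "broad_genes": sorted(truth.broad_genes),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        payload = json.load(fh)
    levels = {}
    for key, level in payload.get("true_editing_levels", {}).items():
        site, sample = key.rsplit("|", 1)
        levels[(site, sample)] = float(level)
    return SyntheticTruth(
        tra_assignment={t: set(g) for t, g in payload["tra_assignment"].items()},
        mirrored_genes=set(payload["mirrored_genes"]),
        restricted_junctions={
            t: set(k) for t, k in payload["restricted_junctions"].items()
        },
        mirrored_junctions={
            t: set(k) for t, k in payload.get("mirrored_junctions", {}).items()
        },
        true_editing_levels=levels,
        hyper_edited_read_ids=set(payload["hyper_edited_read_ids"]),
        housekeeping_genes=set(payload.get("housekeeping_genes", [])),
        broad_genes=set(payload.get("broad_genes", [])),
    )


def read_config_yaml(path: str | Path) -> dict:
    """Load a configuration mapping, rejecting non-mapping documents."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return data
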