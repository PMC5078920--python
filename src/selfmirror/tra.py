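"""Tissue-restricted antigen (TRA) detection and mirroring statistics.

A TRA gene is highly expressed (FPKM > ``high_fpkm``, strict) in exactly one
peripheral tissue and lowly expressed (FPKM < ``low_fpkm``, strict) in every
other peripheral tissue. Reference samples (the mTEC-like populations) are
excluded from both conditions. Values inside the band
[``low_fpkm``, ``high_fpkm``] make a gene neither high nor low: they
disqualify TRA status in that tissue and, in any other tissue, block the
gene's TRA status altogether.

Mirror coverage asks what fraction of each tissue's TRA genes a reference
sample expresses (FPKM above ``expressed_fpkm``). The leave-one-out matrix
asks, for each pair of samples, what fraction of the genes uniquely
expressed in sample 1 (holding sample 2 out of the panel) are also expressed
in sample 2 — the gene-level "self-shadow" of one sample in another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import EXPRESSED_READS_PER_NT, ExpressionPanel

__all__ = ["TraCallConfig", "detect_tra_genes", "mirror_coverage", "leave_one_out_matrix"]


@dataclass(frozen=True)
class TraCallConfig:
    """Thresholds for TRA calling and mirror coverage.

    ``high_fpkm``/``low_fpkm`` define the TRA call (strict inequalities);
    ``expressed_fpkm`` defines "expressed" for mirror coverage;
    ``expressed_reads_per_nt`` defines "expressed" for the leave-one-out
    analysis, which runs on equal-depth count panels rather than FPKM.
    """

    high_fpkm: float = 5.0
    low_fpkm: float = 0.3
    expressed_fpkm: float = 0.3
    expressed_reads_per_nt: float = EXPRESSED_READS_PER_NT
    excluded_samples: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (self.high_fpkm > self.low_fpkm >= 0):
            raise ValueError("require high_fpkm > low_fpkm >= 0")
        object.__setattr__(self, "excluded_samples", frozenset(self.excluded_samples))


def _tissue_samples(panel: ExpressionPanel, config: TraCallConfig) -> list[str]:
    missing = config.excluded_samples - set(panel.samples)
    if missing:
        raise KeyError(f"excluded samples not in panel: {sorted(missing)}")
    return [s for s in panel.samples if s not in config.excluded_samples]


def detect_tra_genes(
    panel: ExpressionPanel, config: TraCallConfig | None = None
) -> dict[str, set[str]]:
    """Call TRA genes per tissue.

    Returns a mapping tissue -> set of gene ids; the sets are pairwise
    disjoint by construction (a gene high in two tissues is a TRA of
    neither).
    """
    config = config or TraCallConfig()
    tissues = _tissue_samples(panel, config)
    if len(tissues) < 2:
        raise ValueError("TRA detection needs at least 2 non-excluded tissues")
    fpkm = panel.fpkm[tissues]
    high = fpkm.to_numpy() > config.high_fpkm
    low = fpkm.to_numpy() < config.low_fpkm
    result: dict[str, set[str]] = {}
    genes = np.asarray(panel.genes, dtype=object)
    for j, t in enumerate(tissues):
        others = [k for k in range(len(tissues)) if k != j]
        mask = high[:, j] & low[:, others].all(axis=1)
        result[t] = set(genes[mask])
    return result


def mirror_coverage(
    tra_sets: dict[str, set[str]],
    panel: ExpressionPanel,
    reference_sample: str,
    expressed_fpkm: float = 0.3,
) -> pd.Series:
    """Fraction of each tissue's TRA genes expressed in ``reference_sample``.

    Expression in the reference means FPKM strictly above ``expressed_fpkm``.
    Tissues with an empty TRA set get NaN (undefined), not zero.
    """
    if reference_sample not in panel.samples:
        raise KeyError(f"unknown reference sample {reference_sample!r}")
    ref = panel.fpkm[reference_sample]
    out = {}
    for tissue, genes in tra_sets.items():
        if not genes:
            out[tissue] = np.nan
            continue
        idx = pd.Index(sorted(genes))
        covered = int((ref.reindex(idx) > expressed_fpkm).sum())
        out[tissue] = covered / len(genes)
    return pd.Series(out, name="mirror_coverage")


def leave_one_out_matrix(
    panel: ExpressionPanel,
    expressed_reads_per_nt: float = EXPRESSED_READS_PER_NT,
) -> pd.DataFrame:
    """Pairwise uniquely-expressed-gene overlap under leave-one-out.

    Entry (t1, t2): hold sample t2 out of the panel; among genes expressed
    (reads/nt > threshold, strict) in t1 and in no other remaining sample,
    the fraction also expressed in t2. The numerator counts genes expressed
    in exactly {t1, t2}; the denominator counts genes expressed in t1 and
    nowhere else except possibly t2. Diagonal and zero-denominator entries
    are NaN. The matrix is asymmetric by construction.

    The panel should be depth-matched (see
    :func:`selfmirror.expression.subsample_counts`) so that "expressed"
    means the same thing in every column.
    """
    samples = panel.samples
    expressed = (panel.reads_per_nt > expressed_reads_per_nt).to_numpy()
    n = len(samples)
    mat = np.full((n, n), np.nan)
    n_expr_per_gene = expressed.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            in_i = expressed[:, i]
            in_j = expressed[:, j]
            # expressed in i and nowhere else except possibly j
            denom_mask = in_i & (n_expr_per_gene - in_j.astype(int) == 1)
            denom = int(denom_mask.sum())
            if denom == 0:
                continue
            numer = int((denom_mask & in_j).sum())
            mat[i, j] = numer / denom
    return pd.DataFrame(mat, index=samples, columns=samples)
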