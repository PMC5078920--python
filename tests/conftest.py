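"""Shared fixtures: small toy panels and the default synthetic dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from selfmirror.expression import ExpressionPanel, GeneModel
from selfmirror.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard study panel: 5 tissues + mTEC-like reference, 5000
    genes, 40 TRAs/tissue mirrored at 0.6, 20 restricted junctions/tissue
    mirrored at 0.4, 500 editing sites."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A fast configuration for tests that regenerate data repeatedly."""
    return SyntheticConfig(
        n_tissues=3,
        n_genes=300,
        frac_housekeeping=0.4,
        tra_per_tissue=10,
        mirror_fraction=0.6,
        library_size=40_000_000,
        restricted_junctions_per_tissue=5,
        n_editing_sites=60,
        n_hyper_reads=20,
        n_background_reads=60,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def make_panel(counts: dict[str, list[float]], lengths: list[int],
               aligned_totals: dict[str, int] | None = None) -> ExpressionPanel:
    """Hand-built panel helper: counts maps sample -> per-gene counts."""
    genes = [f"g{i}" for i in range(len(lengths))]
    frame = pd.DataFrame(counts, index=genes)
    totals = pd.Series(aligned_totals) if aligned_totals else None
    return ExpressionPanel(frame, lengths=pd.Series(lengths, index=genes),
                           aligned_reads_total=totals)


@pytest.fixture
def toy_gene_models():
    """Two genes on one chromosome: gA (3 exons, + strand) then gB (2
    exons, - strand), separated by an intergenic gap."""
    gA = GeneModel("gA", "chr1", "+", ((100, 200), (400, 500), (700, 800)))
    gB = GeneModel("gB", "chr1", "-", ((2000, 2100), (2400, 2500)))
    return {"gA": gA, "gB": gB}
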