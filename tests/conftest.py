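"""Shared fixtures: tiny hand-built panels and phenotype tables."""

from __future__ import annotations

import numpy as np
import pytest

from lohscan.core import GenotypePanel, PhenotypeTable, SnpRecord


def make_panel(
    calls,
    positions=None,
    chrom: str = "6",
    sample_prefix: str = "S",
) -> GenotypePanel:
    """Build a panel from a genotype-code matrix (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    snps = [
        SnpRecord(f"snp{j:04d}", chrom, int(positions[j]), "A", "G") for j in range(m)
    ]
    return GenotypePanel(snps, calls, [f"{sample_prefix}{i:04d}" for i in range(n)])


def make_phen(panel: GenotypePanel, case_mask) -> PhenotypeTable:
    case_mask = np.asarray(case_mask, dtype=bool)
    n = panel.n_samples
    return PhenotypeTable.from_arrays(
        panel.sample_ids,
        np.where(case_mask, "case", "control"),
        np.linspace(30, 60, n),
        np.where(np.arange(n) % 2 == 0, "male", "female"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20110120)
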