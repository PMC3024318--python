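"""Marker-level quality control: call rate, MAF and exact Hardy-Weinberg test.

The HWE test is the conditional exact test (the PLINK default): conditional on
the observed allele counts, the two-sided p-value sums the probabilities of
every heterozygote count no more likely than the observed one.  Filtering uses
the control group for HWE (cases may legitimately deviate under association);
both groups' p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    GenotypePanel,
    PhenotypeTable,
    UndefinedValueError,
)

__all__ = [
    "QcReport",
    "QcThresholds",
    "snp_call_rate",
    "minor_allele_freq",
    "hwe_exact_test",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Screening thresholds: max missingness, min MAF, min control-HWE p."""

    geno_max: float = 0.5
    maf_min: float = 0.01
    hwe_min: float = 0.001

    def __post_init__(self) -> None:
        for name, v in (("geno_max", self.geno_max), ("maf_min", self.maf_min), ("hwe_min", self.hwe_min)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")


@dataclass
class QcReport:
    snp_id: str
    call_rate: float
    maf: float
    hwe_p_cases: float
    hwe_p_controls: float
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)


def snp_call_rate(panel: GenotypePanel, snp_id: str) -> float:
    """Fraction of samples with a non-missing call at ``snp_id``."""
    col = panel.calls[:, panel.snp_index(snp_id)]
    return float(np.mean(col != MISSING))


def minor_allele_freq(
    panel: GenotypePanel, snp_id: str, subset: np.ndarray | None = None
) -> float:
    """Frequency of the less common allele among non-missing alleles (<= 0.5)."""
    col = panel.calls[:, panel.snp_index(snp_id)]
    if subset is not None:
        col = col[np.asarray(subset)]
    ok = col != MISSING
    if not ok.any():
        raise UndefinedValueError(f"{snp_id}: all genotypes missing in subset")
    n_a = int(np.sum(2 - col[ok]))
    total = 2 * int(ok.sum())
    return min(n_a, total - n_a) / total


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic SNP.

    Conditional on the allele counts, P(n_het) follows the distribution of
    heterozygote counts under random mating; the p-value is the summed
    probability of all heterozygote counts whose probability does not exceed
    the observed one.  Uses the stable ratio recurrence
    ``P(h+2)/P(h) = 4 n_AA n_BB / ((h+2)(h+1))``.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    rare = min(n_a, n_b)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(hets))
    # start from the mid-range het count to avoid underflow, then recurse out
    mid = rare * (n_a + n_b - rare) // (n_a + n_b)
    if mid % 2 != rare % 2:
        mid += 1
    idx_mid = int(np.searchsorted(hets, mid))
    probs[idx_mid] = 1.0
    for i in range(idx_mid, len(hets) - 1):  # upward: h -> h+2
        h = hets[i]
        haa = (n_a - h) // 2
        hbb = (n_b - h) // 2
        probs[i + 1] = probs[i] * 4.0 * haa * hbb / ((h + 2.0) * (h + 1.0))
    for i in range(idx_mid, 0, -1):  # downward: h -> h-2
        h = hets[i]
        haa = (n_a - h) // 2
        hbb = (n_b - h) // 2
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (haa + 1.0) * (hbb + 1.0))
    probs /= probs.sum()
    obs = probs[int(np.searchsorted(hets, n_het))]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    return (
        int(np.sum(col == HOM_A)),
        int(np.sum(col == HET)),
        int(np.sum(col == HOM_B)),
    )


def apply_qc(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypePanel, list[QcReport]]:
    """Drop SNPs failing missingness/MAF/HWE screens; report every SNP.

    HWE is evaluated in controls for the filter (reported for cases too);
    MAF uses all samples.  Idempotent: re-applying to the filtered panel
    changes nothing.
    """
    thresholds = thresholds or QcThresholds()
    case = phen.case_mask(panel.sample_ids)
    reports: list[QcReport] = []
    keep: list[int] = []
    for j, snp in enumerate(panel.snps):
        col = panel.calls[:, j]
        call_rate = float(np.mean(col != MISSING))
        reasons: list[str] = []
        if 1.0 - call_rate > thresholds.geno_max:
            reasons.append(f"missingness>{thresholds.geno_max:g}")
        try:
            maf = minor_allele_freq(panel, snp.snp_id)
        except UndefinedValueError:
            maf = float("nan")
            reasons.append("all-missing")
        if maf < thresholds.maf_min or np.isnan(maf):
            reasons.append(f"maf<{thresholds.maf_min:g}")
        p_case = p_ctrl = 1.0
        sub = col[case]
        if (sub != MISSING).any():
            p_case = hwe_exact_test(*_genotype_counts(sub))
        sub = col[~case]
        if (sub != MISSING).any():
            p_ctrl = hwe_exact_test(*_genotype_counts(sub))
        if p_ctrl < thresholds.hwe_min:
            reasons.append(f"hwe_controls<{thresholds.hwe_min:g}")
        passed = not reasons
        reports.append(QcReport(snp.snp_id, call_rate, maf, p_case, p_ctrl, passed, reasons))
        if passed:
            keep.append(j)
    return panel.subset_snps(keep), reports
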