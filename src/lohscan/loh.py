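"""Allelic-imbalance micro-deletion detection from case/control genotypes.

A germline hemizygous deletion makes carriers appear homozygous for the
surviving allele, so a deleted locus shows an excess of homozygous genotypes
in cases.  Per SNP we compare the homozygous-genotype frequency between the
case (T) and control (N) groups: the T/N ratio is their quotient, and a
Pearson chi-square on the 2x2 homozygous/heterozygous x case/control table
gives the significance.  A locus with T/N > 1 and p < alpha (both strict) is
a frequent-LOH locus, and a run of at least ``min_run`` adjacent frequent-LOH
loci in the position-ordered panel is called a micro-deletion region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    HET,
    MISSING,
    GenotypePanel,
    LohTableRow,
    PhenotypeTable,
    SnpRecord,
    UndefinedValueError,
)

__all__ = [
    "LohLocus",
    "MicroDeletionRegion",
    "homozygosity_freq",
    "tn_ratio",
    "homozygosity_test",
    "loh_scan",
    "call_frequent_loh",
    "call_microdeletions",
]


@dataclass
class LohLocus:
    snp_id: str
    f_hom_case: float
    f_hom_ctrl: float
    tn_ratio: float
    chi2: float
    p: float
    is_frequent_loh: bool
    degenerate: bool = False  # zero-margin 2x2 table


@dataclass
class MicroDeletionRegion:
    snp_ids: list[str]
    chrom: str | None = None
    start_pos: int | None = None
    end_pos: int | None = None
    bands: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


def homozygosity_freq(
    panel: GenotypePanel, phen: PhenotypeTable, snp_id: str, group: str
) -> float:
    """Homozygous-genotype fraction among non-missing calls in one group."""
    if group not in {"case", "control"}:
        raise ValueError("group must be 'case' or 'control'")
    case = phen.case_mask(panel.sample_ids)
    col = panel.calls[case if group == "case" else ~case, panel.snp_index(snp_id)]
    ok = col != MISSING
    if not ok.any():
        raise UndefinedValueError(f"{snp_id}: no non-missing calls in {group} group")
    return float(np.mean(col[ok] != HET))


def tn_ratio(f_case: float, f_ctrl: float) -> float:
    """Case-to-control homozygous-frequency ratio."""
    if f_ctrl <= 0:
        raise UndefinedValueError("T/N ratio undefined: control homozygosity is zero")
    return f_case / f_ctrl


def homozygosity_test(
    panel: GenotypePanel, phen: PhenotypeTable, snp_id: str, alpha: float = 0.05
) -> LohLocus:
    """Per-SNP homozygous-vs-heterozygous case/control chi-square (df=1)."""
    case = phen.case_mask(panel.sample_ids)
    col = panel.calls[:, panel.snp_index(snp_id)]
    counts = np.zeros((2, 2))
    for row, mask in ((0, case), (1, ~case)):
        sub = col[mask]
        sub = sub[sub != MISSING]
        if len(sub) == 0:
            raise UndefinedValueError(f"{snp_id}: empty {['case','control'][row]} group")
        counts[row, 0] = np.sum(sub != HET)  # homozygous
        counts[row, 1] = np.sum(sub == HET)
    f_case = counts[0, 0] / counts[0].sum()
    f_ctrl = counts[1, 0] / counts[1].sum()
    degenerate = bool((counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any())
    if degenerate:
        chi2, p = 0.0, 1.0
    else:
        n = counts.sum()
        denom = counts[0].sum() * counts[1].sum() * counts[:, 0].sum() * counts[:, 1].sum()
        if denom <= 0:
            chi2, p, degenerate = 0.0, 1.0, True
        else:
            chi2 = float(n * (counts[0, 0] * counts[1, 1] - counts[0, 1] * counts[1, 0]) ** 2 / denom)
            p = float(stats.chi2.sf(chi2, 1))
    ratio = f_case / f_ctrl if f_ctrl > 0 else np.inf
    return LohLocus(
        snp_id=snp_id,
        f_hom_case=float(f_case),
        f_hom_ctrl=float(f_ctrl),
        tn_ratio=float(ratio),
        chi2=chi2,
        p=p,
        is_frequent_loh=bool(ratio > 1.0 and p < alpha),
        degenerate=degenerate,
    )


def loh_scan(
    panel: GenotypePanel, phen: PhenotypeTable, alpha: float = 0.05
) -> list[LohLocus]:
    """Homozygosity test for every SNP in panel order."""
    return [homozygosity_test(panel, phen, s, alpha) for s in panel.snp_ids]


def call_frequent_loh(loci: list, alpha: float = 0.05) -> list:
    """Frequent-LOH subset: T/N ratio > 1.0 and p < alpha, both strict.

    Accepts either computed :class:`LohLocus` objects or printed-table
    :class:`~lohscan.core.LohTableRow` rows; input order is preserved.
    """
    out = []
    for loc in loci:
        ratio = loc.tn_ratio
        p = loc.p if isinstance(loc, LohLocus) else loc.p_value
        if ratio > 1.0 and p < alpha:
            out.append(loc)
    return out


def call_microdeletions(
    panel_order: list,
    frequent_loh_ids: set[str],
    min_run: int = 3,
) -> list[MicroDeletionRegion]:
    """Maximal runs of >= ``min_run`` adjacent frequent-LOH loci.

    Adjacency means consecutive position in ``panel_order`` — the full
    QC-passed panel, not just the significant loci.  ``panel_order`` may be
    a list of snp_id strings, :class:`~lohscan.core.SnpRecord` objects, or
    :class:`~lohscan.core.LohTableRow` rows (whose bands/genes are carried
    into the region annotation).  Returned regions are disjoint and in
    panel order.
    """
    ids: list[str] = []
    meta: list = []
    for item in panel_order:
        if isinstance(item, str):
            ids.append(item)
            meta.append(None)
        elif isinstance(item, SnpRecord):
            ids.append(item.snp_id)
            meta.append(item)
        elif isinstance(item, LohTableRow):
            ids.append(item.snp_id)
            meta.append(item)
        else:
            raise TypeError(f"unsupported panel_order element: {type(item)!r}")
    unknown = frequent_loh_ids - set(ids)
    if unknown:
        raise ValueError(f"frequent-LOH ids not in panel: {sorted(unknown)[:5]}")

    regions: list[MicroDeletionRegion] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_run:
            members = [meta[i] for i in run]
            region = MicroDeletionRegion(snp_ids=[ids[i] for i in run])
            if all(isinstance(m, SnpRecord) for m in members):
                region.chrom = members[0].chrom
                region.start_pos = members[0].pos
                region.end_pos = members[-1].pos
                region.bands = [m.band for m in members if m.band]
            elif all(isinstance(m, LohTableRow) for m in members):
                region.bands = [m.band for m in members]
                seen: list[str] = []
                for m in members:
                    if m.gene not in seen:
                        seen.append(m.gene)
                region.genes = seen
            regions.append(region)
        run.clear()

    for i, sid in enumerate(ids):
        if sid in frequent_loh_ids:
            run.append(i)
        else:
            flush()
    flush()
    return regions
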