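"""Sliding-window runs-of-homozygosity (ROH) detection.

The scanner follows the PLINK scheme: a fixed-size window of SNPs slides one
SNP at a time; a window is "homozygous" when it contains at most
``window_het_max`` heterozygous and ``window_missing_max`` missing calls.
Each SNP receives the fraction of overlapping homozygous windows (reduced
denominator at panel edges); SNPs at or above ``hit_threshold`` are in-run.
Maximal in-run stretches are split at inter-SNP gaps larger than
``seg_max_gap_kb`` and then kept as segments only if they satisfy the length,
SNP-count and density criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, MISSING, GenotypePanel, PhenotypeTable

__all__ = ["RohParams", "RohSegment", "detect_roh", "roh_summary"]


@dataclass(frozen=True)
class RohParams:
    """Scanning-window and segment criteria (PLINK-style defaults).

    The segment criteria (1000 kb minimum length, 100 SNPs minimum,
    50 kb/SNP maximum density, 1000 kb maximum gap) are the headline
    parameters; the scanning-window internals are the tool defaults.
    """

    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    hit_threshold: float = 0.05
    seg_min_length_kb: float = 1000.0
    seg_min_snps: int = 100
    seg_max_density_kb_per_snp: float = 50.0
    seg_max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.hit_threshold <= 1:
            raise ValueError("hit_threshold must lie in (0, 1]")
        for name in ("window_snps", "window_het_max", "window_missing_max",
                     "seg_min_length_kb", "seg_min_snps",
                     "seg_max_density_kb_per_snp", "seg_max_gap_kb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class RohSegment:
    sample_id: str
    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int
    length_kb: float


def _hom_window_fraction(codes: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-SNP fraction of overlapping windows that are homozygous."""
    n = len(codes)
    w = params.window_snps
    het = (codes == HET).astype(np.int64)
    mis = (codes == MISSING).astype(np.int64)
    c_het = np.concatenate([[0], np.cumsum(het)])
    c_mis = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - w + 1
    starts = np.arange(n_win)
    hom_win = (
        (c_het[starts + w] - c_het[starts] <= params.window_het_max)
        & (c_mis[starts + w] - c_mis[starts] <= params.window_missing_max)
    ).astype(np.int64)
    c_hom = np.concatenate([[0], np.cumsum(hom_win)])
    frac = np.empty(n)
    for i in range(n):
        lo = max(0, i - w + 1)
        hi = min(i, n_win - 1)
        frac[i] = (c_hom[hi + 1] - c_hom[lo]) / (hi - lo + 1)
    return frac


def detect_roh(
    panel: GenotypePanel, sample_id: str, params: RohParams | None = None
) -> list[RohSegment]:
    """ROH segments for one sample, per chromosome."""
    params = params or RohParams()
    i = panel.sample_ids.index(sample_id)
    segments: list[RohSegment] = []
    chroms = sorted({s.chrom for s in panel.snps})
    for chrom in chroms:
        idx = [j for j, s in enumerate(panel.snps) if s.chrom == chrom]
        codes = panel.calls[i, idx]
        pos = np.array([panel.snps[j].pos for j in idx], dtype=np.int64)
        if params.window_snps > len(codes):
            warnings.warn(
                f"window_snps={params.window_snps} exceeds panel size on chrom {chrom}",
                stacklevel=2,
            )
            continue
        frac = _hom_window_fraction(codes, params)
        in_run = frac >= params.hit_threshold
        # maximal in-run stretches, split at oversized gaps first
        k = 0
        n = len(codes)
        while k < n:
            if not in_run[k]:
                k += 1
                continue
            end = k
            while end + 1 < n and in_run[end + 1] and (
                (pos[end + 1] - pos[end]) / 1000.0 <= params.seg_max_gap_kb
            ):
                end += 1
            n_snps = end - k + 1
            length_kb = (pos[end] - pos[k]) / 1000.0
            if (
                n_snps >= params.seg_min_snps
                and length_kb >= params.seg_min_length_kb
                and (length_kb / n_snps) <= params.seg_max_density_kb_per_snp
            ):
                segments.append(
                    RohSegment(sample_id, chrom, int(pos[k]), int(pos[end]), n_snps, length_kb)
                )
            k = end + 1
    return segments


def roh_summary(
    panel: GenotypePanel, phen: PhenotypeTable, params: RohParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample segment counts and per-SNP segment coverage.

    Returns ``(per_sample, per_snp)``: one row per sample (status, number of
    segments, total kb in segments) and one row per SNP (number of samples
    whose segments cover it).
    """
    params = params or RohParams()
    case = phen.case_mask(panel.sample_ids)
    positions = panel.positions
    coverage = np.zeros(panel.n_snps, dtype=np.int64)
    rows = []
    for i, sid in enumerate(panel.sample_ids):
        segs = detect_roh(panel, sid, params)
        for seg in segs:
            hit = np.array(
                [s.chrom == seg.chrom for s in panel.snps]
            ) & (positions >= seg.start_pos) & (positions <= seg.end_pos)
            coverage += hit
        rows.append(
            {
                "sample_id": sid,
                "status": "case" if case[i] else "control",
                "n_segments": len(segs),
                "total_kb": sum(s.length_kb for s in segs),
            }
        )
    per_sample = pd.DataFrame(rows)
    per_snp = pd.DataFrame(
        {"snp_id": panel.snp_ids, "pos": positions, "n_samples_covered": coverage}
    )
    return per_sample, per_snp
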