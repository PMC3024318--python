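"""qPCR relative quantification by the 2^-ddCt method with paired tests.

dCt = Ct(target) - Ct(endogenous control) within a specimen; ddCt is the
difference of dCt between a sample and its reference (tumor vs paired
normal, or a cell line vs the reference line); relative expression is
2^-ddCt, assuming perfect (2.0) amplification efficiency.  Replicate Ct
values are arithmetically averaged before any difference is taken.
Significance across pairs is assessed on the log2 scale (ddCt), with both
the paired t-test and the exact Wilcoxon signed-rank test reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import IntegrityError, UndefinedValueError

__all__ = [
    "CtTable",
    "FoldChangeResult",
    "read_ct_table",
    "delta_delta_ct",
    "paired_tests",
    "cell_line_profile",
]

#: |log2 fold| below which a change is reported as "unchanged" (reporting
#: convenience only; inference always uses the tests)
UNCHANGED_LOG2_FOLD = 0.1

_TISSUES = {"tumor", "normal", "cell_line"}


@dataclass
class CtTable:
    """Long-format Ct measurements: one row per replicate.

    Columns: sample_id, tissue (tumor/normal/cell_line), gene, replicate, ct.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "tissue", "gene", "replicate", "ct"}
        if not required.issubset(self.df.columns):
            raise IntegrityError(f"Ct table needs columns {sorted(required)}")
        bad = set(self.df["tissue"]) - _TISSUES
        if bad:
            raise IntegrityError(f"unknown tissue values: {sorted(bad)}")
        if (self.df["ct"] <= 0).any():
            raise IntegrityError("Ct values must be positive")

    def mean_ct(self, sample_id: str, gene: str, tissue: str | None = None) -> float:
        sub = self.df[(self.df["sample_id"] == sample_id) & (self.df["gene"] == gene)]
        if tissue is not None:
            sub = sub[sub["tissue"] == tissue]
        if sub.empty:
            raise UndefinedValueError(f"no Ct rows for ({sample_id}, {gene}, {tissue})")
        return float(sub["ct"].mean())


def read_ct_table(path) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"))


@dataclass
class FoldChangeResult:
    sample_id: str | None
    delta_ct_sample: float
    delta_ct_ref: float
    delta_delta_ct: float
    fold_change: float
    direction: str  # up / down / unchanged


def _fold(ddct: float, sample_id: str | None, dct_s: float, dct_r: float) -> FoldChangeResult:
    fold = float(2.0 ** (-ddct))
    if abs(ddct) < UNCHANGED_LOG2_FOLD:
        direction = "unchanged"
    else:
        direction = "down" if ddct > 0 else "up"
    return FoldChangeResult(sample_id, dct_s, dct_r, float(ddct), fold, direction)


def delta_delta_ct(
    ct_target_sample,
    ct_control_sample,
    ct_target_ref,
    ct_control_ref,
    sample_id: str | None = None,
) -> FoldChangeResult:
    """Relative expression of a sample vs its reference specimen.

    Each argument is a replicate Ct value or list thereof (averaged first);
    the two "control" arguments are the endogenous-control gene.
    """
    vals = []
    for v in (ct_target_sample, ct_control_sample, ct_target_ref, ct_control_ref):
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 0 or np.isnan(arr).any():
            raise UndefinedValueError("missing Ct value (endogenous control required)")
        vals.append(float(arr.mean()))
    dct_s = vals[0] - vals[1]
    dct_r = vals[2] - vals[3]
    return _fold(dct_s - dct_r, sample_id, dct_s, dct_r)


def paired_tests(pairs: list[tuple[float, float]]) -> dict:
    """Two-sided paired tests on dCt differences across specimen pairs.

    ``pairs`` holds (tumor dCt, normal dCt) per specimen; the per-pair
    difference is the ddCt.  Returns the paired t-test p, the exact Wilcoxon
    signed-rank p (exact for n <= 25 without ties), the count of pairs with
    tumor fold-change < 1 (ddCt > 0), and the total.  If every difference is
    zero the t statistic is undefined and p = 1 is reported with
    ``degenerate=True``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    tumor = np.array([p[0] for p in pairs], dtype=float)
    normal = np.array([p[1] for p in pairs], dtype=float)
    diffs = tumor - normal
    n = len(diffs)
    out = {"n_total": n, "n_down": int(np.sum(diffs > 0)), "degenerate": False}
    if np.allclose(diffs, 0.0):
        out.update({"t_p": 1.0, "wilcoxon_p": 1.0, "t_stat": np.nan, "degenerate": True})
        return out
    t_stat, t_p = stats.ttest_rel(tumor, normal)
    method = "exact" if n <= 25 else "approx"
    try:
        w_p = float(stats.wilcoxon(diffs, method=method).pvalue)
    except ValueError:  # zeros make the exact method unavailable
        w_p = float(stats.wilcoxon(diffs, method="approx").pvalue)
    out.update({"t_stat": float(t_stat), "t_p": float(t_p), "wilcoxon_p": w_p})
    return out


def cell_line_profile(
    ct_table: CtTable,
    reference_line: str,
    control_gene: str = "18S",
) -> pd.DataFrame:
    """Fold change of every target gene in every cell line vs a reference line."""
    df = ct_table.df
    lines = sorted(df.loc[df["tissue"] == "cell_line", "sample_id"].unique())
    if reference_line not in lines:
        raise UndefinedValueError(f"reference line {reference_line!r} not in table")
    genes = sorted(set(df["gene"]) - {control_gene})
    rows = []
    for line in lines:
        for gene in genes:
            res = delta_delta_ct(
                ct_table.mean_ct(line, gene),
                ct_table.mean_ct(line, control_gene),
                ct_table.mean_ct(reference_line, gene),
                ct_table.mean_ct(reference_line, control_gene),
                sample_id=line,
            )
            rows.append(
                {
                    "cell_line": line, "gene": gene,
                    "delta_delta_ct": res.delta_delta_ct,
                    "fold_change": res.fold_change,
                    "direction": res.direction,
                }
            )
    return pd.DataFrame(rows)
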