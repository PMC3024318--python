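"""Single-SNP case-control association: allelic and genotypic chi-square,
covariate-adjusted logistic regression, Bonferroni and max-T permutation.

The allelic test treats each individual as two independent alleles (the PLINK
convention, an approximation under Hardy-Weinberg deviation) and uses the
Pearson chi-square without continuity correction.  Odds-ratio confidence
intervals are Woolf logit intervals; a zero cell triggers the
Haldane-Anscombe +0.5 correction for the OR/CI only, flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypePanel, PhenotypeTable

__all__ = [
    "AssocResult",
    "allelic_test",
    "genotypic_test",
    "logistic_assoc",
    "bonferroni",
    "max_t_permutation",
    "allele_counts",
    "allelic_scan",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class AssocResult:
    snp_id: str | None
    allele_counts: np.ndarray  # 2x2 (case/control x allele A/B) or 2x3 genotypic
    chi2: float
    df: int
    p: float
    or_: float
    ci95: tuple[float, float]
    p_bonferroni: float | None = None
    p_perm: float | None = None
    haldane: bool = False  # OR/CI computed with the +0.5 correction


def _pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction; empty rows/columns
    are dropped (reducing df) rather than producing NaN."""
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 0, 1.0
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    chi2 = float(((t - exp) ** 2 / exp).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def allelic_test(case_a: int, case_b: int, ctrl_a: int, ctrl_b: int) -> AssocResult:
    """2x2 allele-count test with OR and Woolf 95% CI (allele A vs B)."""
    table = np.array([[case_a, case_b], [ctrl_a, ctrl_b]], dtype=float)
    if table.sum() <= 0:
        raise ValueError("empty allele table")
    chi2, df, p = _pearson_chi2(table)
    haldane = bool((table == 0).any())
    t = table + 0.5 if haldane else table
    or_ = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = float(np.sqrt((1.0 / t).sum()))
    ci = (float(or_ * np.exp(-_Z95 * se)), float(or_ * np.exp(_Z95 * se)))
    return AssocResult(None, table, chi2, df, p, float(or_), ci, haldane=haldane)


def genotypic_test(counts: np.ndarray) -> AssocResult:
    """2x3 genotype-count test (case/control x hom_a/het/hom_b), df 2 or fewer.

    The reported OR/CI is the allelic odds ratio implied by the genotype
    counts (each genotype contributing its allele-A dosage).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 3):
        raise ValueError("genotypic test expects a 2x3 table")
    chi2, df, p = _pearson_chi2(counts)
    a = counts @ np.array([2.0, 1.0, 0.0])
    b = counts @ np.array([0.0, 1.0, 2.0])
    allelic = allelic_test(int(a[0]), int(b[0]), int(a[1]), int(b[1]))
    return AssocResult(
        None, counts, chi2, df, p, allelic.or_, allelic.ci95, haldane=allelic.haldane
    )


def bonferroni(p: float, m: int) -> float:
    """Textbook Bonferroni adjustment min(1, m*p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def logistic_assoc(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    snp_id: str,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> dict:
    """Additively coded logistic regression of case status on allele-A dosage.

    Samples with a missing genotype (or missing covariate) are dropped.
    Returns the genotype coefficient with its Wald test; perfect separation
    or non-convergence is reported via ``converged=False`` rather than an
    exception.
    """
    import statsmodels.api as sm

    j = panel.snp_index(snp_id)
    dose = (2.0 - panel.calls[:, j]).astype(float)
    dose[panel.calls[:, j] == MISSING] = np.nan
    y = phen.case_mask(panel.sample_ids).astype(float)
    X = pd.DataFrame({"dosage": dose})
    cov = phen.covariates(panel.sample_ids).reset_index(drop=True)
    if "age" in covariates:
        X["age"] = cov["age"].to_numpy()
    if "sex" in covariates:
        X["sex_male"] = cov["sex_male"].to_numpy()
    ok = ~X.isna().any(axis=1).to_numpy()
    X = sm.add_constant(X[ok], has_constant="add")
    try:
        fit = sm.Logit(y[ok], X).fit(disp=0, maxiter=100, tol=1e-8)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        return {
            "snp_id": snp_id, "beta": np.nan, "se": np.nan, "p_wald": np.nan,
            "or_": np.nan, "ci95": (np.nan, np.nan), "converged": False, "n": int(ok.sum()),
        }
    beta = float(fit.params["dosage"])
    se = float(fit.bse["dosage"])
    return {
        "snp_id": snp_id,
        "beta": beta,
        "se": se,
        "p_wald": float(fit.pvalues["dosage"]),
        "or_": float(np.exp(beta)),
        "ci95": (float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
        "converged": converged,
        "n": int(ok.sum()),
    }


# ---------------------------------------------------------------------------
# panel-wide helpers
# ---------------------------------------------------------------------------


def allele_counts(panel: GenotypePanel, case: np.ndarray) -> np.ndarray:
    """Allele-A/B counts per SNP and group: shape (n_snps, 4) columns
    (case_a, case_b, ctrl_a, ctrl_b)."""
    out = np.empty((panel.n_snps, 4))
    for grp, mask in ((0, case), (1, ~case)):
        calls = panel.calls[mask]
        ok = calls != MISSING
        a = np.where(ok, 2 - calls, 0).sum(axis=0)
        tot = 2 * ok.sum(axis=0)
        out[:, 2 * grp] = a
        out[:, 2 * grp + 1] = tot - a
    return out


def _chi2_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised 2x2 allele chi-square per SNP from (n,4) count columns."""
    a, b, c, d = counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3]
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, chi2, 0.0)


def allelic_scan(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-SNP allelic tests with Bonferroni and optional max-T permutation."""
    case = phen.case_mask(panel.sample_ids)
    counts = allele_counts(panel, case)
    rows = []
    m = panel.n_snps
    for j, snp in enumerate(panel.snps):
        r = allelic_test(*(int(x) for x in counts[j]))
        rows.append(
            {
                "snp_id": snp.snp_id, "chrom": snp.chrom, "pos": snp.pos,
                "case_a": int(counts[j, 0]), "case_b": int(counts[j, 1]),
                "ctrl_a": int(counts[j, 2]), "ctrl_b": int(counts[j, 3]),
                "chi2": r.chi2, "p": r.p, "or": r.or_,
                "l95": r.ci95[0], "u95": r.ci95[1],
                "p_bonf": bonferroni(r.p, m),
            }
        )
    df = pd.DataFrame(rows)
    if n_perm > 0:
        if seed is None:
            raise ValueError("permutation requires a seed")
        perm = max_t_permutation(panel, phen, n_perm=n_perm, seed=seed)
        df["p_perm"] = perm["p_perm"].to_numpy()
        df["p_perm_pointwise"] = perm["p_perm_pointwise"].to_numpy()
    return df


def max_t_permutation(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    statistic=None,
    n_perm: int = 10000,
    seed: int | None = None,
    batch: int = 512,
) -> pd.DataFrame:
    """Family-wise (max-T) and pointwise permutation p-values per SNP.

    Case/control labels are shuffled; for each permutation the per-SNP
    statistic (default: allelic chi-square) is recomputed and compared with
    the observed values.  Adjusted p = (1 + #{perm max >= observed}) /
    (n_perm + 1); pointwise p uses each SNP's own permuted statistics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("permutation requires a seed")
    rng = np.random.default_rng(seed)
    case = phen.case_mask(panel.sample_ids)

    if statistic is None:
        ok = (panel.calls != MISSING)
        a_dose = np.where(ok, 2 - panel.calls, 0).astype(np.float64)
        ok = ok.astype(np.float64)

        def statistic(mask: np.ndarray) -> np.ndarray:
            mask = mask.astype(np.float64)
            case_a = mask @ a_dose
            case_t = 2.0 * (mask @ ok)
            ctrl_a = a_dose.sum(axis=0) - case_a
            ctrl_t = 2.0 * ok.sum(axis=0) - case_t
            counts = np.stack([case_a, case_t - case_a, ctrl_a, ctrl_t - ctrl_a], axis=1)
            return _chi2_from_counts(counts)

    obs = statistic(case)
    n_ge_max = np.zeros(panel.n_snps, dtype=np.int64)
    n_ge_point = np.zeros(panel.n_snps, dtype=np.int64)
    labels = case.copy()
    for start in range(0, n_perm, batch):
        for _ in range(start, min(start + batch, n_perm)):
            rng.shuffle(labels)
            s = statistic(labels)
            n_ge_max += s.max() >= obs
            n_ge_point += s >= obs
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "stat": obs,
            "p_perm": (1.0 + n_ge_max) / (n_perm + 1.0),
            "p_perm_pointwise": (1.0 + n_ge_point) / (n_perm + 1.0),
        }
    )
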