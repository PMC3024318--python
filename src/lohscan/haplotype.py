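"""EM haplotype-frequency estimation, pairwise LD, confidence-interval
haplotype blocks, and sliding-window haplotype association.

Phase is never observed: for each multilocus genotype the EM algorithm sums
over all compatible ordered haplotype pairs, weighting each pair by the
product of current haplotype frequencies (random mating).  The EM is run on
the pooled sample (it never sees case/control labels), and per-stratum
frequencies are posterior-expected haplotype counts within each stratum;
this also makes label permutation valid without re-running the EM.

Haplotypes are encoded as bitmasks over the window SNPs (bit set = allele B)
and rendered as allele strings for reporting.  Individuals with any missing
genotype inside a window are dropped from that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

from .core import MISSING, GenotypePanel, PhenotypeTable, UndefinedValueError

__all__ = [
    "HaplotypeFreqs",
    "LdStats",
    "HaploAssocResult",
    "em_haplotypes",
    "ld_pair",
    "gabriel_blocks",
    "sliding_window_assoc",
    "haplotype_permutation",
    "GABRIEL_RULES",
]


@dataclass
class HaplotypeFreqs:
    snp_ids: list[str]
    haplotypes: list[str]  # allele strings, aligned with frequency vectors
    freq_all: np.ndarray
    freq_cases: np.ndarray
    freq_controls: np.ndarray
    loglik: float
    loglik_trajectory: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    # per-retained-sample expected haplotype counts (rows sum to 2)
    dosages: np.ndarray | None = None
    sample_index: np.ndarray | None = None  # indices into panel.sample_ids


@dataclass
class LdStats:
    snp_pair: tuple[str, str]
    d_prime: float
    r2: float
    ci_low: float
    ci_high: float


@dataclass
class HaploAssocResult:
    snp_ids: list[str]
    haplotype: str
    freq_case: float
    freq_ctrl: float
    chi2: float
    p: float
    p_perm: float | None = None


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[int, int]]:
    """All unordered haplotype-bitmask pairs consistent with a genotype
    vector (codes 0 hom_a / 1 het / 2 hom_b per SNP)."""
    het_sites = [k for k, g in enumerate(geno) if g == 1]
    base = 0
    for k, g in enumerate(geno):
        if g == 2:
            base |= 1 << k
    if not het_sites:
        return [(base, base)]
    pairs = set()
    for assign in product((0, 1), repeat=len(het_sites)):
        h1, h2 = base, base
        for site, bit in zip(het_sites, assign):
            if bit:
                h1 |= 1 << site
            else:
                h2 |= 1 << site
        pairs.add((min(h1, h2), max(h1, h2)))
    return sorted(pairs)


def _window_genotypes(
    panel: GenotypePanel, snp_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype-code matrix restricted to samples complete in the window."""
    idx = [panel.snp_index(s) for s in snp_ids]
    sub = panel.calls[:, idx]
    keep = ~(sub == MISSING).any(axis=1)
    if not keep.any():
        raise UndefinedValueError("no sample has complete genotypes in window")
    return sub[keep], np.flatnonzero(keep)


def em_haplotypes(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    snp_ids: list[str],
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies for a 2-8 SNP window.

    Converges when the largest frequency change falls below ``tol``; the
    log-likelihood is checked to be non-decreasing at every iteration.
    Deterministic: initialisation is uniform over compatible haplotypes.
    """
    if not 2 <= len(snp_ids) <= 8:
        raise ValueError("EM window must span 2-8 SNPs")
    sub, sample_index = _window_genotypes(panel, snp_ids)

    genos, counts = np.unique(sub, axis=0, return_counts=True)
    pair_lists = [_compatible_pairs(tuple(g)) for g in genos]
    hap_set = sorted({h for pl in pair_lists for p in pl for h in p})
    hap_pos = {h: i for i, h in enumerate(hap_set)}
    H = len(hap_set)

    freqs = np.full(H, 1.0 / H)
    loglik_traj: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new = np.zeros(H)
        loglik = 0.0
        for pl, c in zip(pair_lists, counts):
            w = np.array(
                [(2.0 if h1 != h2 else 1.0) * freqs[hap_pos[h1]] * freqs[hap_pos[h2]] for h1, h2 in pl]
            )
            tot = w.sum()
            if tot <= 0:  # degenerate start; re-spread uniformly
                w[:] = 1.0
                tot = w.sum()
            loglik += c * np.log(tot)
            w *= c / tot
            for (h1, h2), wi in zip(pl, w):
                new[hap_pos[h1]] += wi
                new[hap_pos[h2]] += wi
        new /= new.sum()
        if loglik_traj and loglik < loglik_traj[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        loglik_traj.append(loglik)
        delta = np.max(np.abs(new - freqs))
        freqs = new
        if delta < tol:
            converged = True
            break

    # posterior haplotype dosages per distinct genotype -> per sample
    geno_dose = np.zeros((len(genos), H))
    for gi, pl in enumerate(pair_lists):
        w = np.array(
            [(2.0 if h1 != h2 else 1.0) * freqs[hap_pos[h1]] * freqs[hap_pos[h2]] for h1, h2 in pl]
        )
        w /= w.sum()
        for (h1, h2), wi in zip(pl, w):
            geno_dose[gi, hap_pos[h1]] += wi
            geno_dose[gi, hap_pos[h2]] += wi
    # map each retained sample to its distinct-genotype row
    _, inverse = np.unique(sub, axis=0, return_inverse=True)
    dosages = geno_dose[inverse]

    case = phen.case_mask(panel.sample_ids)[sample_index]
    n_case, n_ctrl = int(case.sum()), int((~case).sum())
    freq_cases = dosages[case].sum(axis=0) / (2 * n_case) if n_case else np.full(H, np.nan)
    freq_controls = dosages[~case].sum(axis=0) / (2 * n_ctrl) if n_ctrl else np.full(H, np.nan)

    idx = [panel.snp_index(s) for s in snp_ids]
    labels = [
        "".join(
            panel.snps[idx[k]].allele_b if (h >> k) & 1 else panel.snps[idx[k]].allele_a
            for k in range(len(snp_ids))
        )
        for h in hap_set
    ]
    return HaplotypeFreqs(
        snp_ids=list(snp_ids),
        haplotypes=labels,
        freq_all=freqs,
        freq_cases=freq_cases,
        freq_controls=freq_controls,
        loglik=loglik_traj[-1],
        loglik_trajectory=loglik_traj,
        n_iter=n_iter,
        converged=converged,
        dosages=dosages,
        sample_index=sample_index,
    )


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------


def _two_locus_loglik(genos: np.ndarray, counts: np.ndarray, hap_freqs: np.ndarray) -> float:
    """Log-likelihood of two-locus genotype data given the four haplotype
    frequencies (order 00, 01, 10, 11 as bitmasks: bit0 = SNP i, bit1 = SNP j)."""
    ll = 0.0
    for g, c in zip(genos, counts):
        pl = _compatible_pairs(tuple(g))
        p = sum(
            (2.0 if h1 != h2 else 1.0) * hap_freqs[h1] * hap_freqs[h2] for h1, h2 in pl
        )
        if p <= 0:
            return -np.inf
        ll += c * np.log(p)
    return ll


def ld_pair(
    panel: GenotypePanel,
    snp_i: str,
    snp_j: str,
    phen: PhenotypeTable | None = None,
    grid_points: int = 101,
) -> LdStats:
    """D' and r-squared from EM two-locus frequencies, with a likelihood-
    profile confidence interval on D'.

    The profile fixes the allele frequencies at their sample estimates,
    sweeps D' over a uniform grid with the sign of the point estimate, and
    reads the 5th/95th percentiles of the normalised profile likelihood.
    """
    if phen is None:
        # EM itself never uses labels; build an all-control stand-in
        phen = PhenotypeTable.from_arrays(
            panel.sample_ids, ["control"] * panel.n_samples,
            [np.nan] * panel.n_samples, ["female"] * panel.n_samples,
        )
    est = em_haplotypes(panel, phen, [snp_i, snp_j])
    f = np.zeros(4)
    for lab, fr in zip(est.haplotypes, est.freq_all):
        i1 = panel.snp_index(snp_i)
        j1 = panel.snp_index(snp_j)
        b0 = int(lab[0] == panel.snps[i1].allele_b)
        b1 = int(lab[1] == panel.snps[j1].allele_b)
        f[b0 | (b1 << 1)] = fr
    p_a = f[0] + f[2]  # allele A at snp_i
    p_b = f[0] + f[1]  # allele A at snp_j
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 0:
        raise UndefinedValueError(f"LD undefined: monomorphic SNP in ({snp_i},{snp_j})")
    d = f[0] - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / dmax if dmax > 0 else 0.0
    d_prime = min(d_prime, 1.0)
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))

    sub, _ = _window_genotypes(panel, [snp_i, snp_j])
    genos, counts = np.unique(sub, axis=0, return_counts=True)
    sign = 1.0 if d >= 0 else -1.0
    grid = np.linspace(0.0, 1.0, grid_points)
    lls = np.empty(grid_points)
    for k, dp in enumerate(grid):
        dd = sign * dp * dmax
        hf = np.array(
            [p_a * p_b + dd, p_b * (1 - p_a) - dd, p_a * (1 - p_b) - dd, (1 - p_a) * (1 - p_b) + dd]
        )
        hf = np.clip(hf, 0.0, 1.0)
        s = hf.sum()
        lls[k] = _two_locus_loglik(genos, counts, hf / s) if s > 0 else -np.inf
    w = np.exp(lls - lls.max())
    cdf = np.cumsum(w) / w.sum()
    ci_low = float(grid[int(np.searchsorted(cdf, 0.05))])
    ci_high = float(grid[min(int(np.searchsorted(cdf, 0.95)), grid_points - 1)])
    return LdStats((snp_i, snp_j), float(d_prime), float(min(r2, 1.0)), ci_low, ci_high)


# ---------------------------------------------------------------------------
# Confidence-interval (Gabriel-style) blocks
# ---------------------------------------------------------------------------

#: classification thresholds on the D' confidence interval (Gabriel rule);
#: size-dependent relaxations used by Haploview for very short blocks are
#: not applied — blocks of any size use the headline rule.
GABRIEL_RULES = {
    "strong_ci_low": 0.70,
    "strong_ci_high": 0.98,
    "recomb_ci_high": 0.90,
    "min_strong_fraction": 0.95,
}


def gabriel_blocks(
    panel: GenotypePanel,
    snp_ids: list[str] | None = None,
    rules: dict | None = None,
) -> list[list[str]]:
    """Partition a region into haplotype blocks by the D' CI rule.

    A pair is "strong LD" when its D' CI is (>= 0.70, >= 0.98) and "strong
    recombination" when the upper bound is < 0.90; a candidate block needs a
    strong-LD outermost pair and >= 95% strong-LD among informative pairs.
    Candidates are accepted longest-first without overlap, so returned
    blocks never share SNPs.
    """
    rules = {**GABRIEL_RULES, **(rules or {})}
    ids = snp_ids if snp_ids is not None else panel.snp_ids
    m = len(ids)
    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                ld = ld_pair(panel, ids[i], ids[j])
            except UndefinedValueError:
                continue
            is_strong = (
                ld.ci_low >= rules["strong_ci_low"] and ld.ci_high >= rules["strong_ci_high"]
            )
            is_recomb = ld.ci_high < rules["recomb_ci_high"]
            strong[i, j] = is_strong
            informative[i, j] = is_strong or is_recomb
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if not strong[i, j]:
                continue
            inf = int(informative[i : j + 1, i : j + 1].sum())
            if inf == 0:
                continue
            st = int(strong[i : j + 1, i : j + 1].sum())
            if st / inf >= rules["min_strong_fraction"]:
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append([ids[k] for k in range(i, j + 1)])
    blocks.sort(key=lambda b: ids.index(b[0]))
    return blocks


# ---------------------------------------------------------------------------
# Sliding-window haplotype association
# ---------------------------------------------------------------------------


def _chi2_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0 or n <= 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _window_tests(
    est: HaplotypeFreqs, case: np.ndarray, rare_freq: float
) -> list[HaploAssocResult]:
    """Per-haplotype 2x2 tests from EM-expected counts; haplotypes rarer
    than ``rare_freq`` overall are pooled into one "RARE" group."""
    mask = case[est.sample_index]
    n_case, n_ctrl = int(mask.sum()), int((~mask).sum())
    case_counts = est.dosages[mask].sum(axis=0)
    ctrl_counts = est.dosages[~mask].sum(axis=0)
    common = est.freq_all >= rare_freq
    groups: list[tuple[str, float, float]] = []
    order = sorted(np.flatnonzero(common), key=lambda k: est.haplotypes[k])
    for k in order:
        groups.append((est.haplotypes[k], case_counts[k], ctrl_counts[k]))
    if (~common).any() and est.freq_all[~common].sum() > 0:
        groups.append(("RARE", case_counts[~common].sum(), ctrl_counts[~common].sum()))
    out = []
    for label, ca, co in groups:
        chi2, p = _chi2_2x2(ca, 2 * n_case - ca, co, 2 * n_ctrl - co)
        out.append(
            HaploAssocResult(
                snp_ids=est.snp_ids,
                haplotype=label,
                freq_case=ca / (2 * n_case) if n_case else np.nan,
                freq_ctrl=co / (2 * n_ctrl) if n_ctrl else np.nan,
                chi2=chi2,
                p=p,
            )
        )
    return out


def sliding_window_assoc(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    window_size: int = 3,
    n_perm: int = 0,
    seed: int | None = None,
    rare_freq: float = 0.01,
) -> list[HaploAssocResult]:
    """Haplotype association in windows of ``window_size`` SNPs, shifting one
    SNP at a time; optionally max-T permutation-adjusted p-values."""
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    case = phen.case_mask(panel.sample_ids)
    windows = [
        panel.snp_ids[k : k + window_size]
        for k in range(panel.n_snps - window_size + 1)
    ]
    ests = [em_haplotypes(panel, phen, w) for w in windows]
    results: list[HaploAssocResult] = []
    per_window: list[list[HaploAssocResult]] = []
    for est in ests:
        r = _window_tests(est, case, rare_freq)
        per_window.append(r)
        results.extend(r)
    if n_perm > 0:
        adj = haplotype_permutation(
            panel, phen, windows=ests, n_perm=n_perm, seed=seed, rare_freq=rare_freq
        )
        for r, p_adj in zip(results, adj):
            r.p_perm = p_adj
    return results


def haplotype_permutation(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    windows: list[HaplotypeFreqs] | list[list[str]],
    n_perm: int = 10000,
    seed: int | None = None,
    rare_freq: float = 0.01,
) -> np.ndarray:
    """Max-T adjusted p per (window, haplotype), in window-then-haplotype
    order matching :func:`sliding_window_assoc` output.

    Because the EM never sees labels, per-sample haplotype dosages are fixed
    across permutations; only the case/control labels are shuffled.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("permutation requires a seed")
    rng = np.random.default_rng(seed)
    ests: list[HaplotypeFreqs] = [
        w if isinstance(w, HaplotypeFreqs) else em_haplotypes(panel, phen, w)
        for w in windows
    ]
    case = phen.case_mask(panel.sample_ids)

    def stats_for(mask: np.ndarray) -> np.ndarray:
        chunks = []
        for est in ests:
            sub = mask[est.sample_index]
            n_case, n_ctrl = int(sub.sum()), int((~sub).sum())
            ca = sub.astype(float) @ est.dosages
            co = est.dosages.sum(axis=0) - ca
            common = est.freq_all >= rare_freq
            order = sorted(np.flatnonzero(common), key=lambda k: est.haplotypes[k])
            vals = [ _chi2_2x2(ca[k], 2 * n_case - ca[k], co[k], 2 * n_ctrl - co[k])[0] for k in order ]
            if (~common).any() and est.freq_all[~common].sum() > 0:
                car = ca[~common].sum()
                cor = co[~common].sum()
                vals.append(_chi2_2x2(car, 2 * n_case - car, cor, 2 * n_ctrl - cor)[0])
            chunks.append(np.array(vals))
        return np.concatenate(chunks)

    obs = stats_for(case)
    n_ge = np.zeros(len(obs), dtype=np.int64)
    labels = case.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        n_ge += stats_for(labels).max() >= obs
    return (1.0 + n_ge) / (n_perm + 1.0)
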