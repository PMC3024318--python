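"""Haplotype EM, pairwise LD and block/window association.

The EM is checked against phase counting (no ambiguity), a brute-force
one-parameter likelihood grid (two loci), and simulation recovery from a
known haplotype pool.
"""

from __future__ import annotations

import numpy as np
import pytest

from lohscan.core import HET, HOM_A, HOM_B, UndefinedValueError
from lohscan.haplotype import (
    em_haplotypes,
    gabriel_blocks,
    ld_pair,
    sliding_window_assoc,
)
from lohscan.simulate import BlockSpec, SimConfig, simulate_panel

from conftest import make_panel, make_phen


def two_locus_grid_oracle(panel, phen):
    """Brute-force ML for two loci: allele freqs are fixed by the genotype
    margins, leaving the AB-haplotype frequency as the single free parameter;
    scan it on a fine grid and return the argmax frequency vector."""
    from lohscan.haplotype import _compatible_pairs, _window_genotypes

    sub, _ = _window_genotypes(panel, panel.snp_ids[:2])
    genos, counts = np.unique(sub, axis=0, return_counts=True)
    p_a = np.mean(2 - sub[:, 0]) / 2  # freq of allele A at locus 1
    p_b = np.mean(2 - sub[:, 1]) / 2
    best, best_ll = None, -np.inf
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    for f_ab in np.linspace(lo, hi, 20001):
        f = np.array(
            [f_ab, p_b - f_ab, p_a - f_ab, 1 - p_a - p_b + f_ab]
        )  # order: bitmask 00,01,10,11 with bit0=locus1 allele B
        if f.min() < -1e-12:
            continue
        f = np.clip(f, 0, 1)
        ll = 0.0
        ok = True
        for g, c in zip(genos, counts):
            pl = _compatible_pairs(tuple(g))
            p = sum((2.0 if h1 != h2 else 1.0) * f[h1] * f[h2] for h1, h2 in pl)
            if p <= 0:
                ok = False
                break
            ll += c * np.log(p)
        if ok and ll > best_ll:
            best_ll, best = ll, f
    return best


class TestEm:
    def test_unambiguous_phase_equals_counting(self):
        # 4 doubly homozygous AA/BB individuals plus one single-het
        calls = np.array(
            [[HOM_A, HOM_A], [HOM_A, HOM_A], [HOM_B, HOM_B], [HOM_B, HOM_B], [HOM_A, HET]],
            dtype=np.int8,
        )
        panel = make_panel(calls)
        phen = make_phen(panel, [True, True, False, False, True])
        est = em_haplotypes(panel, phen, panel.snp_ids)
        freqs = dict(zip(est.haplotypes, est.freq_all))
        assert freqs["AA"] == pytest.approx(5 / 10, abs=1e-9)
        assert freqs["GG"] == pytest.approx(4 / 10, abs=1e-9)
        assert freqs["AG"] == pytest.approx(1 / 10, abs=1e-9)

    def test_matches_two_locus_grid_oracle(self):
        cfg = SimConfig(seed=21, n_cases=100, n_controls=100, n_snps=2,
                        region=("6", 6_100_000, 6_200_000),
                        blocks=[BlockSpec(("AA", "AG", "GA", "GG"), (0.4, 0.3, 0.2, 0.1))],
                        missing_rate=0.0)
        panel, phen, _ = simulate_panel(cfg)
        est = em_haplotypes(panel, phen, panel.snp_ids)
        oracle = two_locus_grid_oracle(panel, phen)
        got = dict(zip(est.haplotypes, est.freq_all))
        # oracle order: bitmask with bit k = allele B of SNP k (panel labels)
        s0, s1 = panel.snps[0], panel.snps[1]
        for h in range(4):
            lab = (s0.allele_b if h & 1 else s0.allele_a) + (
                s1.allele_b if h & 2 else s1.allele_a
            )
            assert got.get(lab, 0.0) == pytest.approx(oracle[h], abs=1e-4)

    def test_three_snp_pool_recovery(self):
        cfg = SimConfig(seed=22, n_cases=1000, n_controls=1000, n_snps=3,
                        region=("6", 6_100_000, 6_300_000),
                        blocks=[BlockSpec(("AAA", "AAG", "AGA", "GGG"), (0.5, 0.3, 0.15, 0.05))],
                        missing_rate=0.0)
        panel, phen, _ = simulate_panel(cfg)
        est = em_haplotypes(panel, phen, panel.snp_ids)
        got = dict(zip(est.haplotypes, est.freq_all))
        for hap, truth in [("AAA", 0.5), ("AAG", 0.3), ("AGA", 0.15), ("GGG", 0.05)]:
            assert got[hap] == pytest.approx(truth, abs=0.02)

    def test_loglik_monotone_and_freqs_sum_to_one(self):
        cfg = SimConfig(seed=23, n_cases=80, n_controls=80, n_snps=4,
                        region=("6", 6_100_000, 6_400_000), missing_rate=0.05)
        panel, phen, _ = simulate_panel(cfg)
        est = em_haplotypes(panel, phen, panel.snp_ids)
        traj = np.array(est.loglik_trajectory)
        assert (np.diff(traj) >= -1e-9).all()
        for vec in (est.freq_all, est.freq_cases, est.freq_controls):
            assert vec.sum() == pytest.approx(1.0, abs=1e-6)
            assert (vec >= -1e-12).all()

    def test_window_size_limits(self):
        panel = make_panel(np.zeros((4, 10), dtype=np.int8))
        phen = make_phen(panel, [True, True, False, False])
        with pytest.raises(ValueError):
            em_haplotypes(panel, phen, panel.snp_ids[:1])
        with pytest.raises(ValueError):
            em_haplotypes(panel, phen, panel.snp_ids[:9])


class TestLd:
    def test_perfect_coupling(self):
        calls = np.array([[HOM_A, HOM_A]] * 5 + [[HOM_B, HOM_B]] * 5 + [[HET, HET]] * 4,
                         dtype=np.int8)
        panel = make_panel(calls)
        ld = ld_pair(panel, "snp0000", "snp0001")
        assert ld.d_prime == pytest.approx(1.0, abs=1e-6)
        assert ld.r2 == pytest.approx(1.0, abs=1e-6)
        assert ld.ci_low <= ld.ci_high

    def test_independent_snps_have_low_r2(self):
        cfg = SimConfig(seed=24, n_cases=1000, n_controls=1000, n_snps=2,
                        region=("6", 6_100_000, 6_200_000), missing_rate=0.0)
        panel, phen, _ = simulate_panel(cfg)
        ld = ld_pair(panel, panel.snp_ids[0], panel.snp_ids[1], phen)
        assert ld.r2 < 0.01

    def test_r2_invariant_to_allele_relabeling(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([HOM_A, HET, HOM_B], size=(200, 2), p=[0.36, 0.48, 0.16]).astype(np.int8)
        panel = make_panel(calls)
        swapped = calls.copy()
        swapped[:, 0] = np.where(calls[:, 0] == HOM_A, HOM_B,
                                 np.where(calls[:, 0] == HOM_B, HOM_A, HET))
        panel2 = make_panel(swapped)
        r1 = ld_pair(panel, "snp0000", "snp0001").r2
        r2 = ld_pair(panel2, "snp0000", "snp0001").r2
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_monomorphic_is_undefined(self):
        calls = np.array([[HOM_A, HET]] * 10, dtype=np.int8)
        panel = make_panel(calls)
        with pytest.raises(UndefinedValueError):
            ld_pair(panel, "snp0000", "snp0001")


class TestBlocks:
    def test_single_pool_block_of_three(self):
        cfg = SimConfig(seed=25, n_cases=1000, n_controls=1000, n_snps=3,
                        region=("6", 6_100_000, 6_300_000),
                        blocks=[BlockSpec(("AAA", "GGG"), (0.7, 0.3))], missing_rate=0.0)
        panel, _, _ = simulate_panel(cfg)
        blocks = gabriel_blocks(panel)
        assert blocks == [panel.snp_ids]

    def test_independent_snps_yield_no_blocks(self):
        cfg = SimConfig(seed=26, n_cases=1000, n_controls=1000, n_snps=3,
                        region=("6", 6_100_000, 6_300_000), missing_rate=0.0)
        panel, _, _ = simulate_panel(cfg)
        assert gabriel_blocks(panel) == []

    def test_blocks_never_overlap(self):
        cfg = SimConfig(seed=27, n_cases=400, n_controls=400, n_snps=6,
                        region=("6", 6_100_000, 6_600_000),
                        blocks=[BlockSpec(("AAA", "GGG"), (0.6, 0.4)),
                                BlockSpec(("AAA", "GGG"), (0.5, 0.5))],
                        missing_rate=0.0)
        panel, _, _ = simulate_panel(cfg)
        blocks = gabriel_blocks(panel)
        seen: set[str] = set()
        for b in blocks:
            assert not (seen & set(b))
            seen |= set(b)


class TestSlidingWindow:
    def test_complete_ld_window_matches_single_snp_test(self):
        from lohscan.association import allele_counts, allelic_test

        cfg = SimConfig(seed=28, n_cases=300, n_controls=300, n_snps=3,
                        region=("6", 6_100_000, 6_300_000),
                        blocks=[BlockSpec(("AAA", "GGG"), (0.7, 0.3), (0.6, 0.4))],
                        missing_rate=0.0)
        panel, phen, _ = simulate_panel(cfg)
        res = sliding_window_assoc(panel, phen)
        p_hap = min(r.p for r in res if r.haplotype == "AAA")
        counts = allele_counts(panel, phen.case_mask(panel.sample_ids))[0]
        p_snp = allelic_test(*(int(x) for x in counts)).p
        assert np.isclose(p_hap, p_snp, rtol=1e-4)

    def test_risk_haplotype_is_detected(self):
        cfg = SimConfig(seed=29, n_cases=360, n_controls=360, n_snps=3,
                        region=("6", 29_523_000, 29_601_000),
                        blocks=[BlockSpec(("AAA", "GGG"), (0.733, 0.267), (0.822, 0.178))],
                        missing_rate=0.0)
        panel, phen, _ = simulate_panel(cfg)
        res = sliding_window_assoc(panel, phen)
        aaa = [r for r in res if r.haplotype == "AAA"][0]
        assert aaa.freq_case > aaa.freq_ctrl
        assert aaa.p < 0.05

    def test_permutation_floor_and_dominance(self):
        cfg = SimConfig(seed=30, n_cases=80, n_controls=80, n_snps=4,
                        region=("6", 6_100_000, 6_400_000), missing_rate=0.0)
        panel, phen, _ = simulate_panel(cfg)
        res = sliding_window_assoc(panel, phen, window_size=3, n_perm=199, seed=5)
        for r in res:
            assert r.p_perm >= 1 / 200 - 1e-12
            assert r.p_perm >= r.p - 0.02  # family-wise adjustment dominates
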