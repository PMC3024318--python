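"""Synthetic genotype, phenotype and qPCR data with the structure the
analysis assumes.

The generator emulates a matched case-control design on a single chromosome
arm: individuals are two haplotypes drawn per LD block from a specified
haplotype pool (blocks are independent of each other), disease status comes
either from a logistic risk model on a designated risk haplotype or from
block-specific case haplotype frequencies (retrospective sampling), and the
two signals the region-scanning stages look for are implanted mechanically:

* hemizygous micro-deletion carriers lose one haplotype over a SNP span and
  are typed as homozygous for the surviving allele (never as missing) —
  exactly the genotyping behaviour the T/N homozygosity statistic presumes;
* autozygous (ROH) samples have their second haplotype copied from the
  first over a tract.

Defaults follow the emulated study: 360 cases / 360 controls, 233 evenly
spaced SNPs on chr6p between 6,095,364 and 30,048,467 bp, ~2% missingness,
control genotypes in Hardy-Weinberg equilibrium.  All randomness flows from
the single mandatory config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GenotypePanel,
    IntegrityError,
    PhenotypeTable,
    SnpRecord,
    _relabel_minor_allele,
    write_ped_map,
)

__all__ = [
    "BlockSpec",
    "RiskSpec",
    "DeletionSpec",
    "RohImplantSpec",
    "SimConfig",
    "simulate_panel",
    "simulate_ct_table",
    "write_fixture_suite",
]

# demographic defaults of the emulated cohort (age mean/sd, male fraction)
_CASE_AGE = (46.4, 11.2)
_CTRL_AGE = (41.4, 8.9)
_CASE_MALE_FRAC = 0.718
_CTRL_MALE_FRAC = 0.344


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: haplotype allele strings with their frequencies.

    ``freqs_cases`` optionally gives a different pool for case chromosomes
    (retrospective sampling of a case-enriched haplotype).
    """

    haplotypes: tuple[str, ...]
    freqs: tuple[float, ...]
    freqs_cases: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        L = {len(h) for h in self.haplotypes}
        if len(L) != 1:
            raise IntegrityError("block haplotypes must share a length")
        for fr in (self.freqs, self.freqs_cases):
            if fr is None:
                continue
            if len(fr) != len(self.haplotypes):
                raise IntegrityError("one frequency per haplotype required")
            if abs(sum(fr) - 1.0) > 1e-6 or min(fr) < 0:
                raise IntegrityError("block frequencies must be a distribution")
        for k in range(len(self.haplotypes[0])):
            letters = {h[k] for h in self.haplotypes}
            if len(letters) > 2:
                raise IntegrityError(f"site {k} in block is not biallelic")

    @property
    def n_snps(self) -> int:
        return len(self.haplotypes[0])


@dataclass(frozen=True)
class RiskSpec:
    """Logistic disease model on one haplotype: log-OR per copy."""

    block: int
    haplotype: int
    odds_ratio: float


@dataclass(frozen=True)
class DeletionSpec:
    """Hemizygous deletion implant over ``n_snps`` SNPs starting at ``start``."""

    start: int
    n_snps: int
    carrier_freq_cases: float
    carrier_freq_controls: float


@dataclass(frozen=True)
class RohImplantSpec:
    """Autozygous tract implant in ``n_samples`` samples."""

    n_samples: int
    start: int
    n_snps: int


@dataclass
class SimConfig:
    seed: int
    n_cases: int = 360
    n_controls: int = 360
    n_snps: int = 233
    region: tuple[str, int, int] = ("6", 6_095_364, 30_048_467)
    blocks: list[BlockSpec] | None = None
    risk: RiskSpec | None = None
    deletion: DeletionSpec | None = None
    roh: RohImplantSpec | None = None
    missing_rate: float = 0.02


def _default_blocks(n_snps: int, rng: np.random.Generator) -> list[BlockSpec]:
    """Independent biallelic SNPs with MAF ~ Uniform(0.05, 0.5)."""
    mafs = rng.uniform(0.05, 0.5, size=n_snps)
    return [BlockSpec(("A", "G"), (1.0 - m, m)) for m in mafs]


def _resolve_blocks(config: SimConfig, rng: np.random.Generator) -> list[BlockSpec]:
    blocks = config.blocks or _default_blocks(config.n_snps, rng)
    total = sum(b.n_snps for b in blocks)
    if total != config.n_snps:
        raise IntegrityError(
            f"blocks cover {total} SNPs but config.n_snps={config.n_snps}"
        )
    return blocks


def _draw_haplotypes(
    blocks: list[BlockSpec],
    n_ind: int,
    rng: np.random.Generator,
    use_case_freqs: bool,
) -> np.ndarray:
    """(n_ind, 2, n_snps) matrix of allele indices (0 = first letter)."""
    n_snps = sum(b.n_snps for b in blocks)
    out = np.empty((n_ind, 2, n_snps), dtype=np.int8)
    col = 0
    for b in blocks:
        freqs = b.freqs_cases if (use_case_freqs and b.freqs_cases) else b.freqs
        # allele index per haplotype per site: 0 for the alphabetically
        # first letter observed at that site
        letters = [sorted({h[k] for h in b.haplotypes}) for k in range(b.n_snps)]
        hap_idx = np.array(
            [[letters[k].index(h[k]) for k in range(b.n_snps)] for h in b.haplotypes],
            dtype=np.int8,
        )
        draws = rng.choice(len(b.haplotypes), size=(n_ind, 2), p=freqs)
        out[:, :, col : col + b.n_snps] = hap_idx[draws]
        col += b.n_snps
    return out


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypePanel, PhenotypeTable, dict]:
    """Generate a genotype panel, phenotypes, and a record of every implant."""
    rng = np.random.default_rng(config.seed)
    blocks = _resolve_blocks(config, rng)
    n_snps = config.n_snps
    n_total = config.n_cases + config.n_controls

    if config.deletion is not None:
        d = config.deletion
        if d.start < 0 or d.start + d.n_snps > n_snps:
            raise IntegrityError("deletion span outside panel")
    if config.roh is not None:
        r = config.roh
        if r.start < 0 or r.start + r.n_snps > n_snps:
            raise IntegrityError("ROH tract outside panel")

    if config.risk is not None:
        haps, case_mask = _draw_with_logistic_risk(config, blocks, rng)
    else:
        case_haps = _draw_haplotypes(blocks, config.n_cases, rng, use_case_freqs=True)
        ctrl_haps = _draw_haplotypes(blocks, config.n_controls, rng, use_case_freqs=False)
        haps = np.concatenate([case_haps, ctrl_haps], axis=0)
        case_mask = np.zeros(n_total, dtype=bool)
        case_mask[: config.n_cases] = True

    truth: dict = {"seed": config.seed}

    if config.deletion is not None:
        d = config.deletion
        span = slice(d.start, d.start + d.n_snps)
        carrier = np.zeros(n_total, dtype=bool)
        carrier[case_mask] = rng.random(case_mask.sum()) < d.carrier_freq_cases
        carrier[~case_mask] = rng.random((~case_mask).sum()) < d.carrier_freq_controls
        # hemizygous carriers: second haplotype lost, typed as homozygous
        haps[carrier, 1, span] = haps[carrier, 0, span]
        truth["deletion_carriers"] = np.flatnonzero(carrier).tolist()
        truth["deletion_span"] = [d.start, d.start + d.n_snps - 1]

    if config.roh is not None:
        r = config.roh
        tract = slice(r.start, r.start + r.n_snps)
        chosen = rng.choice(n_total, size=r.n_samples, replace=False)
        haps[chosen, 1, tract] = haps[chosen, 0, tract]
        truth["roh_samples"] = sorted(int(i) for i in chosen)
        truth["roh_tract"] = [r.start, r.start + r.n_snps - 1]

    calls = haps.sum(axis=1).astype(np.int8)  # allele-index sum = code 0/1/2
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    chrom, start, end = config.region
    positions = np.linspace(start, end, n_snps).round().astype(np.int64)
    if len(np.unique(positions)) != n_snps:
        raise IntegrityError("region too small for the requested SNP count")
    snps = []
    col = 0
    for bi, b in enumerate(blocks):
        for k in range(b.n_snps):
            letters = sorted({h[k] for h in b.haplotypes})
            a = letters[0]
            bb = letters[1] if len(letters) > 1 else "N"
            snps.append(SnpRecord(f"snp{col:04d}", chrom, int(positions[col]), a, bb))
            col += 1

    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    age = np.where(
        case_mask,
        rng.normal(*_CASE_AGE, size=n_total),
        rng.normal(*_CTRL_AGE, size=n_total),
    ).round(1)
    age = np.clip(age, 14, 80)
    male = np.where(
        case_mask,
        rng.random(n_total) < _CASE_MALE_FRAC,
        rng.random(n_total) < _CTRL_MALE_FRAC,
    )
    phen = PhenotypeTable.from_arrays(
        sample_ids,
        np.where(case_mask, "case", "control"),
        age,
        np.where(male, "male", "female"),
    )
    panel = GenotypePanel(snps, calls, sample_ids)
    # same convention as file loading: allele A is the control-minor allele
    _relabel_minor_allele(panel, phen)
    truth["case_samples"] = np.flatnonzero(case_mask).tolist()
    return panel, phen, truth


def _draw_with_logistic_risk(
    config: SimConfig, blocks: list[BlockSpec], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample fixed case/control quotas under a logistic model.

    P(disease) = expit(b0 + ln(OR) * copies of the risk haplotype), with b0
    chosen so the marginal disease probability is ~0.5 (matched design).
    """
    from scipy.special import expit

    spec = config.risk
    beta = float(np.log(spec.odds_ratio))
    b = blocks[spec.block]
    b0 = -beta * 2.0 * b.freqs[spec.haplotype]

    need_case, need_ctrl = config.n_cases, config.n_controls
    kept_haps: list[np.ndarray] = []
    kept_case: list[np.ndarray] = []
    guard = 0
    offset = sum(bl.n_snps for bl in blocks[: spec.block])
    target = np.array(
        [blocks[spec.block].haplotypes[spec.haplotype][k] for k in range(b.n_snps)]
    )
    letters = [sorted({h[k] for h in b.haplotypes}) for k in range(b.n_snps)]
    target_idx = np.array([letters[k].index(target[k]) for k in range(b.n_snps)], dtype=np.int8)

    while (need_case > 0 or need_ctrl > 0) and guard < 200:
        guard += 1
        batch = max(1024, 2 * (need_case + need_ctrl))
        haps = _draw_haplotypes(blocks, batch, rng, use_case_freqs=False)
        seg = haps[:, :, offset : offset + b.n_snps]
        copies = (seg == target_idx).all(axis=2).sum(axis=1)
        disease = rng.random(batch) < expit(b0 + beta * copies)
        take_case = np.flatnonzero(disease)[:need_case]
        take_ctrl = np.flatnonzero(~disease)[:need_ctrl]
        need_case -= len(take_case)
        need_ctrl -= len(take_ctrl)
        kept_haps.append(haps[np.concatenate([take_case, take_ctrl])])
        flags = np.zeros(len(take_case) + len(take_ctrl), dtype=bool)
        flags[: len(take_case)] = True
        kept_case.append(flags)
    if need_case > 0 or need_ctrl > 0:
        raise IntegrityError("could not fill case/control quotas")
    haps = np.concatenate(kept_haps, axis=0)
    case_mask = np.concatenate(kept_case)
    order = np.argsort(~case_mask, kind="stable")  # cases first, deterministic
    return haps[order], case_mask[order]


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    n_pairs: int = 11,
    delta_delta_ct_mean: float = 0.0,
    sd: float = 1.0,
    n_replicates: int = 2,
    seed: int | None = None,
    target_gene: str = "TARGET",
    control_gene: str = "18S",
):
    """Paired tumor/normal Ct table with a tumor dCt shift.

    Per pair the normal-tissue dCt is N(14, 0.75) around an abundant
    endogenous control (base Ct 11) and the tumor dCt adds a biological
    shift N(delta_delta_ct_mean, sd); replicates add N(0, 0.15) technical
    noise.  Positive shift means lower tumor expression (fold < 1).
    """
    from .expression import CtTable

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pairs):
        sid = f"P{i:02d}"
        dct_normal = 14.0 + rng.normal(0, 0.75)
        dct_tumor = dct_normal + rng.normal(delta_delta_ct_mean, sd)
        for tissue, dct in (("normal", dct_normal), ("tumor", dct_tumor)):
            ct_ctrl = 11.0 + rng.normal(0, 0.5)
            for gene, ct in ((control_gene, ct_ctrl), (target_gene, ct_ctrl + dct)):
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "sample_id": sid, "tissue": tissue, "gene": gene,
                            "replicate": rep + 1,
                            "ct": round(ct + rng.normal(0, 0.15), 4),
                        }
                    )
    return CtTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Canonical fixture suite
# ---------------------------------------------------------------------------


def write_fixture_suite(out_dir: str | Path, seed: int = 20110120) -> dict:
    """Write the canonical test fixtures (PED/MAP panels, Ct table, LOH CSV)
    and a manifest recording every derived seed."""
    from importlib import resources

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    sub = {name: int(root.integers(2**31)) for name in
           ("null", "risk", "deletion", "roh", "ct")}

    manifest: dict = {"seed": seed, "sub_seeds": sub, "files": []}

    def emit(name: str, config: SimConfig) -> None:
        panel, phen, truth = simulate_panel(config)
        write_ped_map(panel, phen, out / f"{name}.ped", out / f"{name}.map",
                      out / f"{name}.covar.tsv")
        manifest["files"] += [f"{name}.ped", f"{name}.map", f"{name}.covar.tsv"]
        manifest[name] = {k: truth[k] for k in truth if k != "seed"}

    emit("null", SimConfig(seed=sub["null"]))
    emit(
        "risk",
        SimConfig(
            seed=sub["risk"],
            n_snps=3,
            region=("6", 29_523_000, 29_601_000),
            blocks=[BlockSpec(("AAA", "GGG"), (0.733, 0.267), (0.822, 0.178))],
        ),
    )
    emit(
        "deletion",
        SimConfig(
            seed=sub["deletion"],
            n_snps=12,
            region=("6", 6_095_364, 7_300_000),
            blocks=[BlockSpec(("A", "G"), (0.7, 0.3)) for _ in range(12)],
            deletion=DeletionSpec(4, 4, 0.20, 0.05),
            missing_rate=0.0,
        ),
    )
    emit(
        "roh",
        SimConfig(
            seed=sub["roh"],
            n_cases=10,
            n_controls=10,
            n_snps=300,
            region=("6", 6_100_000, 9_090_000),
            roh=RohImplantSpec(5, 50, 200),
            missing_rate=0.0,
        ),
    )
    ct = simulate_ct_table(11, 1.5, 1.0, seed=sub["ct"], target_gene="NEDD9")
    ct.df.to_csv(out / "ct_pairs.tsv", sep="\t", index=False)
    manifest["files"].append("ct_pairs.tsv")

    with resources.as_file(resources.files("lohscan.data").joinpath("table1_loh.csv")) as p:
        (out / "loh_table.csv").write_text(Path(p).read_text())
    manifest["files"].append("loh_table.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
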