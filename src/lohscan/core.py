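"""Genotype/phenotype data model and PLINK-text (PED/MAP) I/O.

Genotype calls are stored as a dense ``n_samples x n_snps`` int8 matrix with
codes ``HOM_A=0`` (two copies of allele A), ``HET=1``, ``HOM_B=2`` and
``MISSING=-1``.  After loading, allele A is re-labelled to be the minor allele
among controls, so that odds-ratio directions are deterministic across files.
Coordinates are 1-based base pairs, as in MAP files; intervals are closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

HOM_A = 0
HET = 1
HOM_B = 2
MISSING = -1


class LohscanError(Exception):
    """Base class for all package errors."""


class ParseError(LohscanError):
    """Malformed input file."""


class IntegrityError(LohscanError):
    """Input violates a structural contract (duplicate ids, wrong row count...)."""


class UndefinedValueError(LohscanError):
    """A requested quantity is undefined for the given data (e.g. all-missing)."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic marker: id, position and the two observed alleles."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    band: str | None = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise IntegrityError(f"{self.snp_id}: position must be positive")
        if self.allele_a == self.allele_b:
            raise IntegrityError(f"{self.snp_id}: alleles must differ")


@dataclass
class GenotypePanel:
    """An ordered SNP panel with per-sample genotype calls.

    SNPs are kept sorted by (chrom, pos); construction re-sorts if needed and
    sorting is idempotent.
    """

    snps: list[SnpRecord]
    calls: np.ndarray  # int8, n_samples x n_snps
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise IntegrityError("calls must be a 2-D matrix")
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise IntegrityError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate snp_id in panel")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IntegrityError("duplicate sample_id in panel")
        order = sorted(range(len(self.snps)), key=lambda i: (self.snps[i].chrom, self.snps[i].pos))
        if order != list(range(len(self.snps))):
            self.snps = [self.snps[i] for i in order]
            self.calls = self.calls[:, order]

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown snp_id: {snp_id}") from None

    def subset_snps(self, keep: Sequence[int] | Sequence[str]) -> "GenotypePanel":
        if keep and isinstance(keep[0], str):
            keep = [self.snp_index(s) for s in keep]  # type: ignore[arg-type]
        keep = list(keep)
        return GenotypePanel(
            [self.snps[i] for i in keep], self.calls[:, keep].copy(), list(self.sample_ids)
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypePanel":
        keep = list(keep)
        return GenotypePanel(
            list(self.snps), self.calls[keep, :].copy(), [self.sample_ids[i] for i in keep]
        )

    def a_dosage(self) -> np.ndarray:
        """Copies of allele A per sample x SNP (float, NaN where missing)."""
        d = (2.0 - self.calls).astype(float)
        d[self.calls == MISSING] = np.nan
        return d


@dataclass
class PhenotypeTable:
    """Per-sample case/control status plus age and sex covariates."""

    df: pd.DataFrame  # index: sample_id; columns: status, age, sex

    def __post_init__(self) -> None:
        required = {"status", "age", "sex"}
        if not required.issubset(self.df.columns):
            raise IntegrityError(f"phenotype table needs columns {sorted(required)}")
        if self.df.index.has_duplicates:
            raise IntegrityError("duplicate sample_id in phenotype table")
        bad = set(self.df["status"]) - {"case", "control"}
        if bad:
            raise IntegrityError(f"unknown status values: {sorted(bad)}")

    @classmethod
    def from_arrays(
        cls,
        sample_ids: Sequence[str],
        status: Sequence[str],
        age: Sequence[float],
        sex: Sequence[str],
    ) -> "PhenotypeTable":
        df = pd.DataFrame(
            {"status": list(status), "age": list(age), "sex": list(sex)},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return cls(df)

    def case_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean case indicator aligned to ``sample_ids`` order."""
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise IntegrityError(f"samples without phenotype rows: {missing[:5]}")
        return (self.df.loc[list(sample_ids), "status"] == "case").to_numpy()

    def covariates(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        sub = self.df.loc[list(sample_ids), ["age", "sex"]].copy()
        sub["sex_male"] = (sub.pop("sex") == "male").astype(float)
        return sub


@dataclass(frozen=True)
class LohTableRow:
    """One row of the printed frequent-LOH summary table."""

    snp_id: str
    band: str
    tn_ratio: float
    p_value: float
    gene: str
    in_microdeletion: bool

    def __post_init__(self) -> None:
        if not self.tn_ratio > 0:
            raise IntegrityError(f"{self.snp_id}: T/N ratio must be positive")
        if not 0.0 <= self.p_value <= 1.0:
            raise IntegrityError(f"{self.snp_id}: p-value outside [0,1]")


# ---------------------------------------------------------------------------
# PED/MAP I/O
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female"}
_STATUS = {"1": "control", "2": "case"}


def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 4:
            raise ParseError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(f)}")
        rows.append((f[0], f[1], int(f[3])))
    ids = [r[1] for r in rows]
    if len(set(ids)) != len(ids):
        raise IntegrityError(f"{map_path}: duplicate snp_id")
    return rows


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    covar_path: str | Path | None = None,
) -> tuple[GenotypePanel, PhenotypeTable]:
    """Load a PLINK-text fileset into a panel and phenotype table.

    Sex and phenotype use PLINK codes (1/2); anything else is an error since
    the downstream covariate-adjusted analyses require complete data.  Ages
    come from an optional two-column covariate file (sample_id, age) and are
    NaN when absent.  After parsing, allele A at each SNP is re-labelled to
    the minor allele among controls.
    """
    map_rows = _read_map(map_path)
    n_snps = len(map_rows)

    sample_ids: list[str] = []
    status: list[str] = []
    sex: list[str] = []
    # first/second allele letter observed at each SNP
    alleles: list[list[str]] = [[] for _ in range(n_snps)]
    raw: list[list[tuple[str, str]]] = []

    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * n_snps:
            raise ParseError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields, got {len(f)}"
            )
        sample_ids.append(f[1])
        if f[4] not in _SEX:
            raise ParseError(f"{ped_path}:{ln}: unknown sex code {f[4]!r}")
        if f[5] not in _STATUS:
            raise ParseError(f"{ped_path}:{ln}: unknown phenotype code {f[5]!r}")
        sex.append(_SEX[f[4]])
        status.append(_STATUS[f[5]])
        geno = []
        for j in range(n_snps):
            a1, a2 = f[6 + 2 * j], f[7 + 2 * j]
            if (a1 == "0") != (a2 == "0"):
                raise ParseError(f"{ped_path}:{ln}: half-missing genotype at SNP {j + 1}")
            geno.append((a1, a2))
            for a in (a1, a2):
                if a != "0" and a not in alleles[j]:
                    alleles[j].append(a)
                    if len(alleles[j]) > 2:
                        raise ParseError(
                            f"{ped_path}: SNP {map_rows[j][1]} has >2 alleles"
                        )
        raw.append(geno)

    if len(set(sample_ids)) != len(sample_ids):
        raise IntegrityError(f"{ped_path}: duplicate sample_id")

    calls = np.full((len(raw), n_snps), MISSING, dtype=np.int8)
    snps = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        obs = alleles[j]
        a = obs[0] if obs else "A"
        b = obs[1] if len(obs) > 1 else ("N" if a != "N" else "M")  # monomorphic placeholder
        for i, geno in enumerate(raw):
            a1, a2 = geno[j]
            if a1 == "0":
                continue
            calls[i, j] = {0: HOM_A, 1: HET, 2: HOM_B}[(a1 != a) + (a2 != a)]
        snps.append(SnpRecord(snp_id, chrom, pos, a, b))

    ages = np.full(len(sample_ids), np.nan)
    if covar_path is not None:
        cov = pd.read_csv(covar_path, sep="\t")
        cov = cov.set_index(cov.columns[0])
        ages = cov.reindex(sample_ids).iloc[:, 0].to_numpy(dtype=float)

    phen = PhenotypeTable.from_arrays(sample_ids, status, ages, sex)
    panel = GenotypePanel(snps, calls, sample_ids)
    _relabel_minor_allele(panel, phen)
    return panel, phen


def _relabel_minor_allele(panel: GenotypePanel, phen: PhenotypeTable) -> None:
    """Make allele A the minor allele among controls (all samples if none)."""
    ctrl = ~phen.case_mask(panel.sample_ids)
    if not ctrl.any():
        ctrl = np.ones(panel.n_samples, dtype=bool)
    calls = panel.calls[ctrl]
    for j, snp in enumerate(panel.snps):
        col = calls[:, j]
        ok = col != MISSING
        if not ok.any():
            continue
        n_a = int(np.sum(2 - col[ok]))
        total = 2 * int(ok.sum())
        # swap when A is the major allele; ties break to the lexicographically
        # smaller letter so the labelling is canonical across files
        if n_a > total - n_a or (2 * n_a == total and snp.allele_a > snp.allele_b):
            swap = panel.calls[:, j]
            hom_a = swap == HOM_A
            swap[swap == HOM_B] = HOM_A
            swap[hom_a] = HOM_B
            panel.snps[j] = replace(snp, allele_a=snp.allele_b, allele_b=snp.allele_a)


def write_ped_map(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    ped_path: str | Path,
    map_path: str | Path,
    covar_path: str | Path | None = None,
) -> None:
    """Write the panel as a PLINK-text fileset (missing genotype -> "0 0")."""
    with open(map_path, "w") as fh:
        for s in panel.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    inv_sex = {v: k for k, v in _SEX.items()}
    inv_status = {v: k for k, v in _STATUS.items()}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            row = phen.df.loc[sid]
            fields = [sid, sid, "0", "0", inv_sex[row["sex"]], inv_status[row["status"]]]
            for j, s in enumerate(panel.snps):
                c = panel.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == HOM_A:
                    fields += [s.allele_a, s.allele_a]
                elif c == HOM_B:
                    fields += [s.allele_b, s.allele_b]
                else:
                    fields += [s.allele_a, s.allele_b]
            fh.write(" ".join(fields) + "\n")
    if covar_path is not None:
        with open(covar_path, "w") as fh:
            fh.write("sample_id\tage\n")
            for sid in panel.sample_ids:
                fh.write(f"{sid}\t{phen.df.loc[sid, 'age']:g}\n")


# ---------------------------------------------------------------------------
# Printed LOH summary-table fixture
# ---------------------------------------------------------------------------

EXPECTED_LOH_TABLE_ROWS = 19


def load_loh_fixture(csv_path: str | Path | None = None) -> list[LohTableRow]:
    """Load the packaged 19-row frequent-LOH summary table (or a copy of it)."""
    if csv_path is None:
        with resources.as_file(
            resources.files("lohscan.data").joinpath("table1_loh.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(csv_path)
    if len(df) != EXPECTED_LOH_TABLE_ROWS:
        raise IntegrityError(
            f"LOH table fixture must have {EXPECTED_LOH_TABLE_ROWS} rows, got {len(df)}"
        )
    rows = []
    for rec in df.itertuples(index=False):
        flag = rec.in_microdeletion
        if isinstance(flag, str):
            flag = flag.strip().lower() in {"true", "1", "yes"}
        rows.append(
            LohTableRow(
                snp_id=rec.snp_id,
                band=rec.band,
                tn_ratio=float(rec.tn_ratio),
                p_value=float(rec.p_value),
                gene=rec.gene,
                in_microdeletion=bool(flag),
            )
        )
    return rows
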