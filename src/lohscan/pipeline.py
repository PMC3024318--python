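"""End-to-end stage orchestration: QC -> association -> haplotype -> LOH ->
ROH -> qPCR, with a JSON run manifest and deterministic outputs.

Stages communicate through files so each is independently re-runnable; a
rerun with the same config and seed is bitwise-identical (no timestamps are
written).  Any stage failure aborts the run with the stage name and cause.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import LohscanError, read_ped_map
from .qc import QcThresholds, apply_qc
from .association import allelic_scan
from .haplotype import gabriel_blocks, sliding_window_assoc
from .loh import call_frequent_loh, call_microdeletions, loh_scan
from .roh import RohParams, roh_summary, detect_roh
from .expression import paired_tests, read_ct_table

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "report_summary"]

_FLOAT_FMT = "%.10g"


class StageError(LohscanError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    ped: str
    map: str
    out_dir: str
    seed: int
    covar: str | None = None
    ct: str | None = None
    # QC
    geno_max: float = 0.5
    maf_min: float = 0.01
    hwe_min: float = 0.001
    # association
    assoc_perm: int = 0
    covariates: bool = True
    # haplotype
    window: int = 3
    haplo_perm: int = 0
    blocks: bool = False
    # LOH
    alpha: float = 0.05
    min_run: int = 3
    # ROH
    roh_params: dict = field(default_factory=dict)
    # qPCR
    control_gene: str = "18S"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }

    def record(stage: str, files: dict[str, int]) -> None:
        manifest["stages"].append({"stage": stage, "outputs": files})

    stage = "load"
    try:
        panel, phen = read_ped_map(config.ped, config.map, config.covar)
        record(stage, {})

        stage = "qc"
        panel_qc, reports = apply_qc(
            panel, phen, QcThresholds(config.geno_max, config.maf_min, config.hwe_min)
        )
        qc_df = pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id, "call_rate": r.call_rate, "maf": r.maf,
                    "hwe_p_cases": r.hwe_p_cases, "hwe_p_controls": r.hwe_p_controls,
                    "passed": r.passed, "fail_reasons": ";".join(r.fail_reasons),
                }
                for r in reports
            ]
        )
        record(stage, {"qc_report.tsv": _write_tsv(qc_df, out / "qc_report.tsv")})

        stage = "assoc"
        assoc = allelic_scan(panel_qc, phen, n_perm=config.assoc_perm, seed=config.seed)
        record(stage, {"assoc.tsv": _write_tsv(assoc, out / "assoc.tsv")})

        stage = "haplo"
        files: dict[str, int] = {}
        if panel_qc.n_snps >= config.window:
            results = sliding_window_assoc(
                panel_qc, phen, window_size=config.window,
                n_perm=config.haplo_perm, seed=config.seed,
            )
            hap_df = pd.DataFrame(
                [
                    {
                        "window": "|".join(r.snp_ids), "haplotype": r.haplotype,
                        "f_case": r.freq_case, "f_ctrl": r.freq_ctrl,
                        "chi2": r.chi2, "p": r.p, "p_perm": r.p_perm,
                    }
                    for r in results
                ]
            )
            files["haplo.tsv"] = _write_tsv(hap_df, out / "haplo.tsv")
        if config.blocks:
            blocks = gabriel_blocks(panel_qc)
            blk_df = pd.DataFrame(
                [{"block": i + 1, "snp_ids": "|".join(b), "n_snps": len(b)}
                 for i, b in enumerate(blocks)]
            )
            files["blocks.tsv"] = _write_tsv(blk_df, out / "blocks.tsv")
        record(stage, files)

        stage = "loh"
        loci = loh_scan(panel_qc, phen, alpha=config.alpha)
        loh_df = pd.DataFrame(
            [
                {
                    "snp_id": l.snp_id, "f_hom_case": l.f_hom_case,
                    "f_hom_ctrl": l.f_hom_ctrl, "tn_ratio": l.tn_ratio,
                    "chi2": l.chi2, "p": l.p, "is_frequent_loh": l.is_frequent_loh,
                }
                for l in loci
            ]
        )
        frequent = {l.snp_id for l in call_frequent_loh(loci, alpha=config.alpha)}
        regions = call_microdeletions(panel_qc.snps, frequent, min_run=config.min_run)
        reg_df = pd.DataFrame(
            [
                {
                    "chrom": r.chrom, "start": r.start_pos, "end": r.end_pos,
                    "n_snps": len(r.snp_ids), "snp_ids": "|".join(r.snp_ids),
                }
                for r in regions
            ],
            columns=["chrom", "start", "end", "n_snps", "snp_ids"],
        )
        record(
            stage,
            {
                "loh.tsv": _write_tsv(loh_df, out / "loh.tsv"),
                "regions.tsv": _write_tsv(reg_df, out / "regions.tsv"),
            },
        )

        stage = "roh"
        params = RohParams(**config.roh_params)
        per_sample, per_snp = roh_summary(panel_qc, phen, params)
        seg_rows = []
        for sid in panel_qc.sample_ids:
            for s in detect_roh(panel_qc, sid, params):
                seg_rows.append(
                    {
                        "sample_id": s.sample_id, "chrom": s.chrom,
                        "start": s.start_pos, "end": s.end_pos,
                        "n_snps": s.n_snps, "length_kb": s.length_kb,
                    }
                )
        seg_df = pd.DataFrame(
            seg_rows, columns=["sample_id", "chrom", "start", "end", "n_snps", "length_kb"]
        )
        record(
            stage,
            {
                "roh_segments.tsv": _write_tsv(seg_df, out / "roh_segments.tsv"),
                "roh_samples.tsv": _write_tsv(per_sample, out / "roh_samples.tsv"),
            },
        )

        stage = "qpcr"
        if config.ct:
            ct = read_ct_table(config.ct)
            df = ct.df
            targets = sorted(set(df["gene"]) - {config.control_gene})
            rows = []
            for gene in targets:
                pairs = []
                for sid in sorted(df.loc[df["tissue"] == "tumor", "sample_id"].unique()):
                    dct_t = ct.mean_ct(sid, gene, "tumor") - ct.mean_ct(sid, config.control_gene, "tumor")
                    dct_n = ct.mean_ct(sid, gene, "normal") - ct.mean_ct(sid, config.control_gene, "normal")
                    pairs.append((dct_t, dct_n))
                res = paired_tests(pairs)
                rows.append({"gene": gene, **{k: res[k] for k in
                                              ("n_total", "n_down", "t_p", "wilcoxon_p")}})
            record(stage, {"qpcr.tsv": _write_tsv(pd.DataFrame(rows), out / "qpcr.tsv")})
        else:
            record(stage, {})
    except LohscanError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage name
        raise StageError(stage, exc) from exc

    checksums = {}
    for st in manifest["stages"]:
        for fname in st["outputs"]:
            checksums[fname] = hashlib.sha256((out / fname).read_bytes()).hexdigest()
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def report_summary(manifest: dict | str | Path, out_dir: str | Path | None = None) -> str:
    """Human-readable Markdown report of a completed run."""
    if not isinstance(manifest, dict):
        out_dir = out_dir or Path(manifest).parent
        manifest = json.loads(Path(manifest).read_text())
    if out_dir is None:
        out_dir = Path(manifest["config"]["out_dir"])
    out = Path(out_dir)
    stages = {s["stage"]: s["outputs"] for s in manifest["stages"]}
    if "qpcr" not in stages:
        raise LohscanError("incomplete manifest: missing stages")

    lines = [f"# lohscan run report (v{manifest['version']}, seed {manifest['seed']})", ""]
    lines.append("## Output files")
    for st in manifest["stages"]:
        for fname, n in st["outputs"].items():
            lines.append(f"- `{fname}` ({st['stage']}, {n} rows)")
    lines.append("")

    assoc = pd.read_csv(out / "assoc.tsv", sep="\t")
    lines.append("## Top single-SNP associations")
    for _, r in assoc.nsmallest(5, "p").iterrows():
        lines.append(f"- {r['snp_id']}: p={r['p']:.3g}, OR={r['or']:.3f}")
    lines.append("")

    if "haplo.tsv" in stages.get("haplo", {}):
        hap = pd.read_csv(out / "haplo.tsv", sep="\t")
        lines.append("## Top haplotypes")
        for _, r in hap.nsmallest(3, "p").iterrows():
            lines.append(
                f"- {r['haplotype']} in [{r['window']}]: p={r['p']:.3g} "
                f"(f_case={r['f_case']:.3f}, f_ctrl={r['f_ctrl']:.3f})"
            )
        lines.append("")

    reg = pd.read_csv(out / "regions.tsv", sep="\t")
    lines.append("## Micro-deletion regions")
    if reg.empty:
        lines.append("no micro-deletions called")
    else:
        for _, r in reg.iterrows():
            lines.append(
                f"- chr{r['chrom']}:{r['start']}-{r['end']} ({r['n_snps']} SNPs)"
            )
    lines.append("")

    seg = pd.read_csv(out / "roh_segments.tsv", sep="\t")
    lines.append("## Runs of homozygosity")
    lines.append(
        f"{len(seg)} segment(s) detected"
        + ("" if len(seg) else " — no ROH across the studied region")
    )
    lines.append("")

    if "qpcr.tsv" in stages.get("qpcr", {}):
        qp = pd.read_csv(out / "qpcr.tsv", sep="\t")
        lines.append("## Expression (paired tumor/normal)")
        for _, r in qp.iterrows():
            verdict = "significant" if r["t_p"] < 0.05 else "not significant"
            lines.append(
                f"- {r['gene']}: down in {r['n_down']}/{r['n_total']} pairs, "
                f"paired-t p={r['t_p']:.3g} ({verdict})"
            )
        lines.append("")
    return "\n".join(lines)
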