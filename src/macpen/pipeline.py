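"""End-to-end composition: QC -> prioritisation -> verdicts -> summaries.

This module assembles the per-stage functions into one deterministic run
driven by a single YAML config. Each stage is importable on its own; the
pipeline only wires them together and writes the results bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coverage, io, mito, penetrance
from .abca4 import Abca4Config
from .filtering import FilterConfig, prioritise
from .model import ProbandGenotype, Severity, Verdict, VerdictStatus
from .penetrance import GenotypeSpec, estimate_penetrance
from .verdicts import assign_verdict, cohort_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run (loaded from YAML)."""

    vcf: Path
    gene_table: Path
    sample_sheet: Path | None = None
    read_stats: Path | None = None
    mtdna_pileup: Path | None = None
    genotype_counts: Path | None = None
    abca4_severity_table: Path | None = None
    primary_gene_overrides: dict[str, str] = field(default_factory=dict)
    filter: FilterConfig = field(default_factory=FilterConfig)
    prevalence: float = penetrance.DEFAULT_PREVALENCE
    cohort_n: int | None = None
    min_avg_coverage: float = coverage.DEFAULT_MIN_AVG_COVERAGE
    mito_target: tuple[str, int, str, str] = mito.DEFAULT_TARGET
    caller_floor: float = mito.DEFAULT_CALLER_FLOOR
    min_depth: int = mito.DEFAULT_MIN_DEPTH
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        inputs = raw.get("inputs", {})
        base = Path(path).parent

        def p(key):
            v = inputs.get(key)
            return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

        fkw = dict(raw.get("filter", {}))
        for key in ("acmg_pass_classes",):
            if key in fkw:
                fkw[key] = frozenset(fkw[key])
        for key in ("known_abca4_variants", "known_div_variants"):
            if key in fkw:
                fkw[key] = frozenset(fkw[key])
        pen = raw.get("penetrance", {})
        mt = raw.get("mito", {})
        target = mt.get("target")
        if isinstance(target, str):
            chrom, pos, ref, alt = target.split(":")
            target = (chrom, int(pos), ref, alt)
        return cls(
            vcf=p("vcf"),
            gene_table=p("gene_table"),
            sample_sheet=p("sample_sheet"),
            read_stats=p("read_stats"),
            mtdna_pileup=p("mtdna_pileup"),
            genotype_counts=p("genotype_counts"),
            abca4_severity_table=p("abca4_severity_table"),
            primary_gene_overrides=raw.get("primary_gene_overrides", {}) or {},
            filter=FilterConfig(**fkw),
            prevalence=float(pen.get("prevalence", penetrance.DEFAULT_PREVALENCE)),
            cohort_n=pen.get("cohort_n"),
            min_avg_coverage=float(
                raw.get("qc", {}).get("min_avg_coverage", coverage.DEFAULT_MIN_AVG_COVERAGE)
            ),
            mito_target=target or mito.DEFAULT_TARGET,
            caller_floor=float(mt.get("caller_floor", mito.DEFAULT_CALLER_FLOOR)),
            min_depth=int(mt.get("min_depth", mito.DEFAULT_MIN_DEPTH)),
            seed=int(raw.get("seed", 0)),
        )


def load_abca4_config(path: str | Path | None) -> Abca4Config:
    """ABCA4 severity assignments from a TSV (hgvs, severity[, reduced_penetrance])."""
    if path is None:
        return Abca4Config()
    df = pd.read_csv(path, sep="\t", dtype=str)
    severity = {
        row.hgvs: Severity.from_label(row.severity) for row in df.itertuples(index=False)
    }
    reduced = frozenset(
        row.hgvs
        for row in df.itertuples(index=False)
        if str(getattr(row, "reduced_penetrance", "0")) in ("1", "True", "true")
    )
    return Abca4Config(
        severity_by_hgvs=severity,
        reduced_penetrance_mild=reduced or Abca4Config().reduced_penetrance_mild,
    )


def build_probands(
    records: list,
    sample_sheet: pd.DataFrame | None = None,
    qc_failed: frozenset[str] = frozenset(),
) -> dict[str, ProbandGenotype]:
    """Group per-sample VCF records into ProbandGenotype objects."""
    phenotypes: dict[str, str] = {}
    sexes: dict[str, str | None] = {}
    probands: dict[str, ProbandGenotype] = {}
    if sample_sheet is not None:
        for row in sample_sheet.itertuples(index=False):
            pid = str(row.proband_id)
            phenotypes[pid] = str(getattr(row, "phenotype", "") or "")
            sexes[pid] = getattr(row, "sex", None)
            probands[pid] = ProbandGenotype(
                proband_id=pid,
                phenotype=phenotypes[pid],
                sex=sexes[pid],
                qc_failed=pid in qc_failed,
            )
    for pid, variant, zygosity in records:
        if pid not in probands:
            probands[pid] = ProbandGenotype(
                proband_id=pid, qc_failed=pid in qc_failed
            )
        probands[pid].variants.append((variant, zygosity))
    return probands


def run_qc(read_stats_path: str | Path, min_avg_coverage: float) -> frozenset[str]:
    """Sample IDs failing coverage QC, from a read-stats TSV."""
    df = pd.read_csv(read_stats_path, sep="\t")
    failed = {
        str(row.sample_id)
        for row in df.itertuples(index=False)
        if not coverage.sample_qc(float(row.avg_smmips_coverage), min_avg_coverage)
    }
    return frozenset(failed)


def run_penetrance_table(
    counts_path: str | Path, cohort_n: int, prevalence: float
) -> list[penetrance.PenetranceEstimate]:
    """Estimates from a genotype-counts TSV (kind, q1[, q2], observed_count[, labels])."""
    df = pd.read_csv(counts_path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        q2 = getattr(row, "q2", None)
        q2 = None if q2 is None or pd.isna(q2) else float(q2)
        labels = tuple(str(getattr(row, "labels", "")).split(";")) if hasattr(row, "labels") else ()
        spec = GenotypeSpec(kind=str(row.kind), q1=float(row.q1), q2=q2, labels=labels)
        out.append(
            estimate_penetrance(
                int(row.observed_count), cohort_n, prevalence, genotype=spec
            )
        )
    return out


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute qc -> filter -> verdicts -> penetrance -> mito -> summary.

    Writes a deterministic results bundle (verdicts TSV, rationale JSON,
    penetrance TSV, heteroplasmy TSV, summary JSON) and returns the summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage qc")
    qc_failed: frozenset[str] = frozenset()
    if cfg.read_stats is not None:
        qc_failed = run_qc(cfg.read_stats, cfg.min_avg_coverage)

    logger.info("stage read inputs")
    genes = io.read_gene_table(cfg.gene_table)
    sheet = io.read_sample_sheet(cfg.sample_sheet) if cfg.sample_sheet else None
    records = io.read_annotated_vcf(cfg.vcf)
    probands = build_probands(records, sheet, qc_failed)

    logger.info("stage filter")
    abca4_cfg = load_abca4_config(cfg.abca4_severity_table)
    prioritised = {
        pid: prioritise(p, genes, cfg.filter) for pid, p in sorted(probands.items())
    }

    logger.info("stage verdicts")
    verdicts: list[Verdict] = [
        assign_verdict(
            p, genes, abca4_cfg, cfg.primary_gene_overrides.get(pid)
        )
        for pid, p in prioritised.items()
    ]

    logger.info("stage penetrance")
    estimates = []
    if cfg.genotype_counts is not None:
        cohort_n = cfg.cohort_n or max(len(verdicts), 1)
        estimates = run_penetrance_table(cfg.genotype_counts, cohort_n, cfg.prevalence)

    logger.info("stage mito")
    het_calls = []
    if cfg.mtdna_pileup is not None:
        pileup = io.read_mtdna_pileup(cfg.mtdna_pileup)
        for row in pileup.itertuples(index=False):
            het_calls.append(
                mito.heteroplasmy_fraction(
                    int(row.ref_count),
                    int(row.alt_count),
                    cfg.min_depth,
                    sample=str(row.sample),
                    position=int(row.position),
                    caller_floor=cfg.caller_floor,
                )
            )

    logger.info("stage summary")
    summary = cohort_summary(verdicts, prioritised, genes, abca4_cfg)
    rp_count, rp_share = penetrance.reduced_penetrance_census(verdicts, prioritised)

    io.write_results(
        verdicts,
        estimates,
        outdir / "verdicts.tsv",
        outdir / "penetrance.tsv" if estimates else None,
        outdir / "rationale.json",
    )
    if het_calls:
        pd.DataFrame(
            [
                {
                    "sample": c.sample,
                    "position": c.position,
                    "ref_count": c.ref_count,
                    "alt_count": c.alt_count,
                    "fraction": "" if c.fraction is None else c.fraction,
                    "reliable": int(c.reliable),
                    "caller_detected": int(c.caller_detected),
                }
                for c in het_calls
            ]
        ).to_csv(outdir / "heteroplasmy.tsv", sep="\t", index=False)
    payload = summary.as_dict()
    payload["reduced_penetrance_carriers"] = {
        "count": rp_count,
        "share_pct": round(100 * rp_share, 1),
    }
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload
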