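"""Synthetic case-ascertained cohorts with the generative structure the
penetrance estimator assumes.

The generator draws population genotypes variant-by-variant under
Hardy-Weinberg proportions (q^2 / 2q(1-q) / (1-q)^2, independent across
variants — the estimator makes the same independence assumption; a complex
cis allele can be emulated as a single composite variant). Disease status is
Bernoulli with the penetrance of the individual's highest-priority causal
genotype, or a background (phenocopy) rate chosen so that the realised
population prevalence matches the target — reflecting that most real probands
are not explained by the panel. Probands are then sampled uniformly from
cases only (case ascertainment), and the cohort can be emitted as an
annotated VCF plus sample sheet through the I/O layer. mtDNA control read
counts are binomial draws at known heteroplasmy and depth.

All stages derive their generators from one global seed via
``numpy.random.SeedSequence`` spawning, so every artefact is reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationSpec, write_annotated_vcf
from .model import Inheritance, Severity, SpliceScores, VariantRecord, Zygosity
from .penetrance import estimate_penetrance


@dataclass(frozen=True)
class SimVariant:
    """One simulated panel variant with its annotations."""

    gene: str
    hgvs: str
    af: float
    acmg_class: int = 5
    consequence: str = "missense"
    inheritance: Inheritance = Inheritance.AR
    severity: Severity | None = None
    splice_scores: SpliceScores | None = None
    chrom: str = "chr1"
    pos: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValueError(f"af {self.af} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.gene}:{self.hgvs}"


@dataclass(frozen=True)
class PenetranceRule:
    """Maps a causal genotype class to its true penetrance.

    kind: homozygous | compound_het | heterozygous | hemizygous. ``variants``
    restricts the rule to specific variant keys; empty means any variant of
    the gene. Rules are matched in list order; an individual's causal
    penetrance is that of the first matching rule.
    """

    gene: str
    kind: str
    penetrance: float
    variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("homozygous", "compound_het", "heterozygous", "hemizygous"):
            raise ValueError(f"unknown genotype kind {self.kind!r}")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError("penetrance must be in [0, 1]")


@dataclass
class MtdnaControl:
    sample: str
    heteroplasmy: float
    depth: int
    position: int = 3243


@dataclass
class SimulationConfig:
    seed: int
    n_population: int
    variants: list[SimVariant]
    penetrance_rules: list[PenetranceRule]
    prevalence_target: float
    n_probands: int
    mtdna: list[MtdnaControl] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.n_probands > self.n_population * self.prevalence_target * 2:
            # loose sanity bound; the exact check happens at ascertainment
            raise ValueError(
                "n_probands exceeds the expected number of cases; "
                "increase n_population or prevalence_target"
            )

    def rngs(self) -> dict[str, np.random.Generator]:
        """Stage generators derived deterministically from the global seed."""
        names = ("population", "disease", "ascertainment", "mtdna")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate_population(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Population genotype table: individuals x variants, codes 0/1/2 alt copies.

    Each variant is drawn independently under Hardy-Weinberg proportions.
    """
    rng = rng if rng is not None else cfg.rngs()["population"]
    n = cfg.n_population
    data = {}
    for v in cfg.variants:
        q = v.af
        p = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
        data[v.key] = rng.choice(3, size=n, p=p / p.sum()).astype(np.int8)
    df = pd.DataFrame(data)
    df.index = [f"IND{i:07d}" for i in range(n)]
    return df


def _causal_penetrance(
    genotypes: pd.DataFrame, cfg: SimulationConfig
) -> np.ndarray:
    """Per-individual penetrance of the first matching causal-genotype rule.

    Individuals matching no rule get NaN (they are phenocopy candidates).
    """
    n = len(genotypes)
    pi = np.full(n, np.nan)
    variants_by_gene: dict[str, list[SimVariant]] = {}
    for v in cfg.variants:
        variants_by_gene.setdefault(v.gene, []).append(v)
    for rule in cfg.penetrance_rules:
        keys = list(rule.variants) or [v.key for v in variants_by_gene.get(rule.gene, [])]
        keys = [k for k in keys if k in genotypes.columns]
        if not keys:
            continue
        g = genotypes[keys].to_numpy()
        if rule.kind == "homozygous":
            match = (g == 2).any(axis=1)
        elif rule.kind == "heterozygous":
            match = (g == 1).any(axis=1)
        elif rule.kind == "hemizygous":
            match = (g >= 1).any(axis=1)
        else:  # compound_het: >=2 distinct het variants in the gene
            match = (g == 1).sum(axis=1) >= 2
        pi = np.where(np.isnan(pi) & match, rule.penetrance, pi)
    return pi


def assign_disease(
    genotypes: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Bernoulli disease status under genotype-specific penetrance.

    Non-causal individuals are cases at the background (phenocopy) rate that
    fills the prevalence target after the expected causal cases. The target
    is unattainable when causal genotypes alone already exceed it.
    """
    rng = rng if rng is not None else cfg.rngs()["disease"]
    pi = _causal_penetrance(genotypes, cfg)
    causal = ~np.isnan(pi)
    n = len(genotypes)
    expected_causal = np.nansum(pi)
    n_noncausal = int(n - causal.sum())
    if n_noncausal == 0:
        background = 0.0
    else:
        background = (cfg.prevalence_target * n - expected_causal) / n_noncausal
    if background < 0.0:
        raise ValueError(
            "prevalence_target unattainable: causal genotypes alone exceed it"
        )
    prob = np.where(causal, pi, background)
    status = rng.random(n) < prob
    return pd.Series(status, index=genotypes.index, name="disease")


def ascertain_probands(
    genotypes: pd.DataFrame,
    disease: pd.Series,
    n_probands: int,
    rng: np.random.Generator | None = None,
    cfg: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Uniform sample (without replacement) of probands from the cases."""
    if rng is None:
        if cfg is None:
            raise ValueError("provide an rng or the config")
        rng = cfg.rngs()["ascertainment"]
    cases = genotypes.index[disease.to_numpy()]
    if len(cases) < n_probands:
        raise ValueError(
            f"insufficient cases: {len(cases)} available, {n_probands} requested"
        )
    chosen = rng.choice(len(cases), size=n_probands, replace=False)
    return genotypes.loc[cases[np.sort(chosen)]]


def simulate_mtdna_counts(
    controls: list[MtdnaControl], rng: np.random.Generator
) -> pd.DataFrame:
    """Binomial alt read counts at known heteroplasmy for control samples."""
    rows = []
    for c in controls:
        if c.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0.0 <= c.heteroplasmy <= 1.0):
            raise ValueError("heteroplasmy must be in [0, 1]")
        alt = int(rng.binomial(c.depth, c.heteroplasmy))
        rows.append(
            {
                "sample": c.sample,
                "position": c.position,
                "ref_count": c.depth - alt,
                "alt_count": alt,
                "true_heteroplasmy": c.heteroplasmy,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "position", "ref_count", "alt_count", "true_heteroplasmy"]
    )


def _sim_variant_record(v: SimVariant, index: int) -> VariantRecord:
    return VariantRecord(
        chrom=v.chrom,
        pos=v.pos or (1000 + 10 * index),
        ref="A",
        alt="G",
        gene=v.gene,
        cdna=v.hgvs,
        consequence=v.consequence,
        gnomad_af=v.af,
        acmg_class=v.acmg_class,
        splice_scores=v.splice_scores,
        abca4_severity=v.severity,
    )


def emit_cohort(
    cohort: pd.DataFrame,
    cfg: SimulationConfig,
    outdir: str | Path,
    annotation_spec: AnnotationSpec | None = None,
) -> dict[str, Path]:
    """Write the ascertained cohort as VCF + sample sheet + gene table + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [_sim_variant_record(v, i) for i, v in enumerate(cfg.variants)]
    key_to_record = {v.key: r for v, r in zip(cfg.variants, records)}
    samples = list(cohort.index)
    genotypes: dict[tuple[str, str], Zygosity] = {}
    for key, rec in key_to_record.items():
        col = cohort[key].to_numpy()
        for s, code in zip(samples, col):
            if code == 1:
                genotypes[(s, rec.key)] = Zygosity.HET
            elif code == 2:
                genotypes[(s, rec.key)] = Zygosity.HOM
    vcf_path = outdir / "cohort.vcf"
    write_annotated_vcf(vcf_path, samples, records, genotypes, annotation_spec)

    sheet = pd.DataFrame(
        {"proband_id": samples, "phenotype": "MD", "prescreened": 0}
    )
    sheet_path = outdir / "sample_sheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)

    gene_rows = {}
    for v in cfg.variants:
        gene_rows[v.gene] = v.inheritance.value
    gene_path = outdir / "gene_table.tsv"
    pd.DataFrame(
        {"gene": list(gene_rows), "inheritance": list(gene_rows.values())}
    ).to_csv(gene_path, sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "n_population": cfg.n_population,
        "n_probands": cfg.n_probands,
        "prevalence_target": cfg.prevalence_target,
        "variants": [
            {"gene": v.gene, "hgvs": v.hgvs, "af": v.af, "acmg_class": v.acmg_class}
            for v in cfg.variants
        ],
        "penetrance_rules": [
            {"gene": r.gene, "kind": r.kind, "penetrance": r.penetrance}
            for r in cfg.penetrance_rules
        ],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "vcf": vcf_path,
        "sample_sheet": sheet_path,
        "gene_table": gene_path,
        "manifest": manifest_path,
    }


def simulate_cohort(cfg: SimulationConfig, outdir: str | Path | None = None):
    """End-to-end: population -> disease -> ascertained cohort (-> files)."""
    rngs = cfg.rngs()
    population = simulate_population(cfg, rngs["population"])
    disease = assign_disease(population, cfg, rngs["disease"])
    cohort = ascertain_probands(population, disease, cfg.n_probands, rngs["ascertainment"])
    paths = emit_cohort(cohort, cfg, outdir) if outdir is not None else {}
    return population, disease, cohort, paths


# ---------------------------------------------------------------------------
# Aggregated replication path for estimator-calibration studies
# ---------------------------------------------------------------------------

def replicate_homozygote_counts(
    q: float,
    true_penetrance: float,
    prevalence: float,
    n_probands: int,
    n_population: int,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Replicated homozygote counts among ascertained probands.

    Exact aggregation of the individual-level model by genotype class
    (individuals within a class are exchangeable): genotype-class counts are
    multinomial under Hardy-Weinberg, disease is binomial per class
    (homozygotes at the true penetrance, everyone else at the background rate
    filling the prevalence target), and the case-only ascertainment of
    ``n_probands`` probands is multivariate hypergeometric. Runs in O(1) per
    replicate, which makes hundreds of replicates at realistic population
    sizes practical.
    """
    if not (0.0 <= q <= 1.0) or not (0.0 <= true_penetrance <= 1.0):
        raise ValueError("q and true_penetrance must be in [0, 1]")
    f_hom = q * q
    background = (prevalence - f_hom * true_penetrance) / (1.0 - f_hom)
    if background < 0.0:
        raise ValueError("prevalence unattainable: homozygote cases alone exceed it")
    rng = np.random.default_rng(seed)
    probs = np.array([f_hom, 2 * q * (1 - q), (1 - q) ** 2])
    out = np.empty(n_replicates, dtype=np.int64)
    for i in range(n_replicates):
        n_hom, n_het, n_ref = rng.multinomial(n_population, probs / probs.sum())
        hom_cases = rng.binomial(n_hom, true_penetrance)
        other_cases = rng.binomial(n_het, background) + rng.binomial(n_ref, background)
        if hom_cases + other_cases < n_probands:
            raise ValueError(
                "insufficient cases in a replicate; increase n_population"
            )
        out[i] = rng.multivariate_hypergeometric(
            [hom_cases, other_cases], n_probands
        )[0]
    return out


def recover_homozygote_penetrance(
    q: float,
    true_penetrance: float,
    prevalence: float,
    n_probands: int,
    n_population: int,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Penetrance estimates over replicated synthetic cohorts.

    Each replicate generates a cohort (see ``replicate_homozygote_counts``)
    and runs the Hardy-Weinberg estimator on the observed homozygote count,
    using the *assumed* prevalence — i.e. the estimator sees exactly what it
    would see on real data. Returns the array of penetrance estimates
    (zero-observation replicates contribute an estimate of 0).
    """
    counts = replicate_homozygote_counts(
        q, true_penetrance, prevalence, n_probands, n_population, n_replicates, seed
    )
    p_x = q * q
    estimates = np.empty(len(counts))
    for i, k in enumerate(counts):
        est = estimate_penetrance(int(k), n_probands, prevalence, p_x)
        estimates[i] = 0.0 if est.penetrance is None else est.penetrance
    return estimates
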