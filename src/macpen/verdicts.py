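"""Per-proband solved-status assignment and cohort summary statistics.

Verdicts follow diagnostic-laboratory convention: "very likely solved" for a
genotype fully compatible with the gene's inheritance mode and built from
(likely) pathogenic variants, "possibly solved" where a variant of uncertain
significance or a reduced-penetrance allele is involved, "unsolved" otherwise
and "failed" for probands whose sequencing failed QC. Without routine
segregation analysis, two distinct rare heterozygous variants in one gene are
presumed compound heterozygous (in trans); experimental phase evidence (e.g.
long-read amplicon sequencing) overrides the presumption.

Each verdict carries machine-readable rule identifiers so the decision path
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .abca4 import Abca4Config, abca4_genotype_verdict
from .model import (
    GeneInfo,
    Inheritance,
    Phase,
    ProbandGenotype,
    Severity,
    TRUNCATING_CONSEQUENCES,
    VariantRecord,
    Verdict,
    VerdictStatus,
    Zygosity,
)

_STATUS_RANK = {
    VerdictStatus.VERY_LIKELY_SOLVED: 2,
    VerdictStatus.POSSIBLY_SOLVED: 1,
}


def presume_phase(
    variants_in_gene: list[tuple[VariantRecord, Zygosity]],
    evidence: Phase | None = None,
) -> Phase:
    """Phase of the variant pair in one gene.

    Experimental evidence (long-read sequencing, segregation) always wins;
    otherwise two or more distinct rare heterozygous variants are presumed in
    trans (compound heterozygous). A single variant, or a homozygous call,
    has no phase to infer.
    """
    if not variants_in_gene:
        raise ValueError("presume_phase requires at least one variant")
    if evidence is not None:
        return evidence
    hets = [(v, z) for v, z in variants_in_gene if z is Zygosity.HET]
    distinct = {v.key for v, _ in hets}
    if len(distinct) >= 2:
        return Phase.PRESUMED_TRANS
    return Phase.UNKNOWN


def _classes(variants: list[VariantRecord]) -> set[int | None]:
    return {v.acmg_class for v in variants}


def _is_45(v: VariantRecord) -> bool:
    return v.acmg_class in (4, 5)


def _abca4_route(
    items: list[tuple[VariantRecord, Zygosity]],
    phase: Phase,
    phenotype: str,
    abca4_cfg: Abca4Config,
) -> tuple[VerdictStatus, str] | None:
    """Route an ABCA4 genotype through the severity grammar if severities known.

    Returns None when severities are unavailable (caller falls back to the
    generic class-based rules) or when the genotype is not biallelic.
    """

    def severity_of(v: VariantRecord) -> Severity | None:
        if v.abca4_severity is not None:
            return v.abca4_severity
        return abca4_cfg.severity_by_hgvs.get(v.cdna)

    def reduced(v: VariantRecord) -> bool:
        return v.cdna in abca4_cfg.reduced_penetrance_mild

    homs = [v for v, z in items if z is Zygosity.HOM]
    if homs:
        sev = severity_of(homs[0])
        if sev is None:
            return None
        return abca4_genotype_verdict(
            sev, sev, phenotype, reduced(homs[0]), reduced(homs[0])
        )
    hets = [v for v, z in items if z is Zygosity.HET]
    if len({v.key for v in hets}) < 2:
        return None
    if phase not in (Phase.TRANS, Phase.PRESUMED_TRANS):
        return None
    a, b = hets[0], next(v for v in hets[1:] if v.key != hets[0].key)
    sa, sb = severity_of(a), severity_of(b)
    if sa is None or sb is None:
        return None
    return abca4_genotype_verdict(sa, sb, phenotype, reduced(a), reduced(b), phase)


def _evaluate_gene(
    gene: str,
    items: list[tuple[VariantRecord, Zygosity]],
    info: GeneInfo | None,
    phase: Phase,
    phenotype: str,
    sex: str | None,
    abca4_cfg: Abca4Config,
) -> tuple[VerdictStatus, str, bool] | None:
    """Best verdict contribution of one gene.

    Returns ``(status, rule_id, counts_as_class45_genotype)`` or None when the
    gene contributes nothing. The boolean feeds the multi-gene flag.
    """
    inheritance = info.inheritance if info is not None else None
    homs = [v for v, z in items if z is Zygosity.HOM]
    hets = [v for v, z in items if z is Zygosity.HET]
    hemis = [v for v, z in items if z is Zygosity.HEMI]

    if gene == "ABCA4":
        routed = _abca4_route(items, phase, phenotype, abca4_cfg)
        if routed is not None:
            status, rule = routed
            if status is VerdictStatus.UNSOLVED:
                return None
            return status, rule, True

    if inheritance is Inheritance.MT:
        if any(_is_45(v) for v in homs + hets + hemis):
            return (
                VerdictStatus.VERY_LIKELY_SOLVED,
                "mt_pathogenic_heteroplasmy_review",
                True,
            )
        return None

    if inheritance is Inheritance.AD:
        if any(_is_45(v) for v in hets + homs):
            return VerdictStatus.VERY_LIKELY_SOLVED, "ad_het_class45", True
        vus = [v for v in hets if v.acmg_class == 3 and v.in_silico_deleterious]
        if vus:
            return VerdictStatus.POSSIBLY_SOLVED, "ad_het_vus_insilico", False
        return None

    if inheritance is Inheritance.XL:
        if any(_is_45(v) for v in hemis):
            return VerdictStatus.VERY_LIKELY_SOLVED, "xl_hemi_class45", True
        if any(_is_45(v) for v in homs):
            return VerdictStatus.VERY_LIKELY_SOLVED, "xl_biallelic_class45", True
        if sex in (None, "F", "female"):
            trunc = [
                v
                for v in hets
                if _is_45(v) and v.consequence in TRUNCATING_CONSEQUENCES
            ]
            if trunc:
                return VerdictStatus.POSSIBLY_SOLVED, "xl_female_het_truncating", False
        return None

    # AR, or unknown inheritance (biallelic genotypes only, capped at possibly)
    unknown = inheritance is None
    biallelic: list[list[VariantRecord]] = []
    if homs:
        biallelic.append([homs[0]])
    distinct_hets = {v.key for v in hets}
    if len(distinct_hets) >= 2 and phase in (Phase.TRANS, Phase.PRESUMED_TRANS):
        a = hets[0]
        b = next(v for v in hets[1:] if v.key != a.key)
        biallelic.append([a, b])
    best: tuple[VerdictStatus, str, bool] | None = None
    for combo in biallelic:
        if all(_is_45(v) for v in combo):
            if unknown:
                cand = (
                    VerdictStatus.POSSIBLY_SOLVED,
                    "unknown_inheritance_biallelic_class45",
                    True,
                )
            else:
                cand = (VerdictStatus.VERY_LIKELY_SOLVED, "ar_biallelic_class45", True)
        elif all(v.acmg_class in (3, 4, 5) for v in combo):
            rule = (
                "unknown_inheritance_biallelic_vus"
                if unknown
                else "ar_biallelic_with_vus"
            )
            cand = (VerdictStatus.POSSIBLY_SOLVED, rule, False)
        else:
            continue
        if best is None or _STATUS_RANK[cand[0]] > _STATUS_RANK[best[0]]:
            best = cand
    return best


def assign_verdict(
    proband: ProbandGenotype,
    genes: dict[str, GeneInfo],
    abca4_cfg: Abca4Config | None = None,
    primary_gene_override: str | None = None,
) -> Verdict:
    """Assign the solved status for one prioritised proband.

    Every gene with retained variants is evaluated under its inheritance
    mode; the proband's verdict is the best per-gene contribution. When
    class-4/5 genotypes exist in more than one gene, all candidate genes are
    reported and the verdict carries a multi-gene flag — the primary gene is
    then taken from ``primary_gene_override`` when supplied (phenotype
    adjudication is a clinical, not computational, step), else the
    best-ranked gene with an alphabetical tie-break for determinism.
    """
    abca4_cfg = abca4_cfg or Abca4Config()
    if proband.qc_failed:
        return Verdict(
            proband_id=proband.proband_id,
            status=VerdictStatus.FAILED,
            rationale=["qc_failed"],
        )
    contributions: list[tuple[VerdictStatus, str, bool, str]] = []
    for gene, items in sorted(proband.by_gene().items()):
        phase = proband.phase.get(gene) or presume_phase(items)
        result = _evaluate_gene(
            gene, items, genes.get(gene), phase, proband.phenotype, proband.sex, abca4_cfg
        )
        if result is not None:
            contributions.append((*result, gene))
    if not contributions:
        return Verdict(
            proband_id=proband.proband_id,
            status=VerdictStatus.UNSOLVED,
            rationale=["no_qualifying_genotype"],
        )
    contributions.sort(key=lambda c: (-_STATUS_RANK[c[0]], c[3]))
    status = contributions[0][0]
    class45_genes = [c[3] for c in contributions if c[2]]
    multi_gene = len(class45_genes) > 1
    candidate_genes = [c[3] for c in contributions]
    if primary_gene_override is not None and primary_gene_override in candidate_genes:
        causal = primary_gene_override
        status = next(c[0] for c in contributions if c[3] == causal)
    else:
        causal = contributions[0][3]
    rationale = [f"{c[3]}:{c[1]}" for c in contributions]
    if multi_gene:
        rationale.append("multi_gene_requires_phenotype_adjudication")
    return Verdict(
        proband_id=proband.proband_id,
        status=status,
        causal_gene=causal,
        rationale=rationale,
        candidate_genes=candidate_genes,
        multi_gene=multi_gene,
    )


def round_half_up_pct(fraction: float, decimals: int = 1) -> float:
    """Percentage with round-half-up at ``decimals`` places (as printed in reports)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n_sequenced: int
    n_failed: int
    n_solved: int
    diagnostic_yield: float
    gene_ranking: list[tuple[str, int, float]]
    inheritance_breakdown: dict[str, tuple[int, float]]
    carrier_counts: dict[str, int]
    multi_gene_probands: int

    def as_dict(self) -> dict:
        return {
            "n_sequenced": self.n_sequenced,
            "n_failed": self.n_failed,
            "n_solved": self.n_solved,
            "diagnostic_yield_pct": round_half_up_pct(self.diagnostic_yield),
            "gene_ranking": [
                {"gene": g, "solved": n, "share_pct": round_half_up_pct(s)}
                for g, n, s in self.gene_ranking
            ],
            "inheritance_breakdown": {
                k: {"solved": n, "share_pct": round_half_up_pct(s)}
                for k, (n, s) in self.inheritance_breakdown.items()
            },
            "carrier_counts": self.carrier_counts,
            "multi_gene_probands": self.multi_gene_probands,
        }


def cohort_summary(
    verdicts: list[Verdict],
    genotypes: dict[str, ProbandGenotype] | None = None,
    genes: dict[str, GeneInfo] | None = None,
    abca4_cfg: Abca4Config | None = None,
    carrier_exclusions: frozenset[str] | None = None,
) -> CohortSummary:
    """Cohort-level summary: yield, gene ranking, inheritance breakdown, carriers.

    diagnostic_yield = n_solved / (n_sequenced - n_failed). Gene shares and
    inheritance shares are over solved probands; ranking is by solved count
    descending with alphabetical tie-break.
    """
    n_sequenced = len(verdicts)
    n_failed = sum(1 for v in verdicts if v.status is VerdictStatus.FAILED)
    solved = [v for v in verdicts if v.solved]
    n_solved = len(solved)
    denominator = n_sequenced - n_failed
    yield_frac = n_solved / denominator if denominator else 0.0

    counts: dict[str, int] = {}
    for v in solved:
        counts[v.causal_gene] = counts.get(v.causal_gene, 0) + 1
    ranking = [
        (g, n, n / n_solved if n_solved else 0.0)
        for g, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]

    inh_counts = {m.value: 0 for m in Inheritance}
    if genes is not None:
        for v in solved:
            info = genes.get(v.causal_gene)
            if info is not None:
                inh_counts[info.inheritance.value] += 1
    inheritance_breakdown = {
        k: (n, n / n_solved if n_solved else 0.0) for k, n in inh_counts.items()
    }

    carriers = {"solved": 0, "unsolved": 0}
    if genotypes is not None and genes is not None:
        carriers = carrier_census(
            verdicts, genotypes, genes, abca4_cfg, carrier_exclusions
        )
    return CohortSummary(
        n_sequenced=n_sequenced,
        n_failed=n_failed,
        n_solved=n_solved,
        diagnostic_yield=yield_frac,
        gene_ranking=ranking,
        inheritance_breakdown=inheritance_breakdown,
        carrier_counts=carriers,
        multi_gene_probands=sum(1 for v in verdicts if v.multi_gene),
    )


#: default carrier-census exclusion: ABCA4 c.2588G>C is benign when not in
#: cis with c.5603A>T, so a lone heterozygous call is not a carrier finding.
DEFAULT_CARRIER_EXCLUSIONS = frozenset({"ABCA4:c.2588G>C"})


def _is_carrier_variant(
    v: VariantRecord,
    genes: dict[str, GeneInfo],
    abca4_cfg: Abca4Config,
    exclusions: frozenset[str],
) -> bool:
    if v.key in exclusions:
        return False
    if v.gene == "ABCA4":
        sev = v.abca4_severity or abca4_cfg.severity_by_hgvs.get(v.cdna)
        if sev is not None:
            return sev in (
                Severity.MILD,
                Severity.MILD_MODERATELY_SEVERE,
                Severity.MODERATELY_SEVERE,
                Severity.SEVERE,
            )
    info = genes.get(v.gene)
    return (
        info is not None
        and info.inheritance is Inheritance.AR
        and v.acmg_class in (4, 5)
    )


def carrier_census(
    verdicts: list[Verdict],
    genotypes: dict[str, ProbandGenotype],
    genes: dict[str, GeneInfo],
    abca4_cfg: Abca4Config | None = None,
    exclusions: frozenset[str] | None = None,
) -> dict[str, int]:
    """Count probands carrying a mono-allelic (likely) pathogenic variant.

    A proband is a carrier when it harbours at least one *heterozygous*
    class-4/5 variant in a recessive-disease gene, or a severity-categorised
    ABCA4 variant, outside its own causal gene. Solved and unsolved cohorts
    are counted separately; a configured exclusion list is skipped.
    """
    abca4_cfg = abca4_cfg or Abca4Config()
    exclusions = DEFAULT_CARRIER_EXCLUSIONS if exclusions is None else exclusions
    out = {"solved": 0, "unsolved": 0}
    by_id = {v.proband_id: v for v in verdicts}
    for pid, geno in genotypes.items():
        verdict = by_id.get(pid)
        if verdict is None or verdict.status is VerdictStatus.FAILED:
            continue
        bucket = "solved" if verdict.solved else "unsolved"
        causal = verdict.causal_gene
        hit = any(
            z is Zygosity.HET
            and v.gene != causal
            and _is_carrier_variant(v, genes, abca4_cfg, exclusions)
            for v, z in geno.variants
        )
        if hit:
            out[bucket] += 1
    return out
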