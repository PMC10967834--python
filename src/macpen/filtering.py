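"""Rare-variant prioritisation cascade.

The cascade mirrors targeted-panel diagnostic practice: copy-number calls are
passed through (they come from a dedicated caller), known pathogenic ABCA4
variants and known deep-intronic variants are extracted regardless of the
generic gates, and remaining SNVs/indels must pass both an inheritance-aware
allele-frequency gate and an ACMG class gate. Variants predicted to alter
splicing (any SpliceAI delta score >= the cutoff) are flagged as splice
candidates.

Frequency gates: biallelic candidates in recessive context pass at a minor
AF <= 0.5%; heterozygous variants in dominant-disease genes at <= 0.1%. A
variant absent from gnomAD (missing AF) is treated as rare and passes — the
study's novel causal candidates were mostly absent from gnomAD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace as dc_replace

from .model import (
    GeneInfo,
    Inheritance,
    ProbandGenotype,
    SpliceScores,
    VariantRecord,
    Zygosity,
)

logger = logging.getLogger(__name__)

# flags attached by prioritise()
FLAG_CNV_EXTERNAL = "cnv_external"
FLAG_KNOWN_ABCA4 = "known_abca4"
FLAG_KNOWN_DIV = "known_div"
FLAG_SPLICE_CANDIDATE = "splice_candidate"
FLAG_UNKNOWN_INHERITANCE = "unknown_inheritance"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the prioritisation cascade.

    af_recessive_max: minor-AF ceiling for homozygous / compound-heterozygous
        candidates (0.005 = 0.5%).
    af_dominant_het_max: minor-AF ceiling for heterozygous variants in
        dominant-disease genes (0.001 = 0.1%).
    ds_min: SpliceAI delta-score floor for splice-candidate flagging.
    acmg_pass_classes: ACMG classes retained (VUS, likely pathogenic,
        pathogenic).
    xl_het_uses_dominant_threshold: evaluate heterozygous variants in
        X-linked genes (female carriers) under the dominant gate; hemizygous
        calls always use the recessive gate.
    """

    af_recessive_max: float = 0.005
    af_dominant_het_max: float = 0.001
    ds_min: float = 0.2
    acmg_pass_classes: frozenset[int] = frozenset({3, 4, 5})
    xl_het_uses_dominant_threshold: bool = True
    use_inhouse_af: bool = False
    known_abca4_variants: frozenset[str] = frozenset()
    known_div_variants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("af_recessive_max", "af_dominant_het_max", "ds_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _af_threshold(
    zygosity: Zygosity, inheritance: Inheritance | None, cfg: FilterConfig
) -> float:
    if zygosity in (Zygosity.HOM, Zygosity.HEMI):
        return cfg.af_recessive_max
    # heterozygous
    if inheritance is Inheritance.AD:
        return cfg.af_dominant_het_max
    if inheritance is Inheritance.XL and cfg.xl_het_uses_dominant_threshold:
        return cfg.af_dominant_het_max
    # AR / MT / unknown: candidate for a biallelic (or heteroplasmic) genotype
    return cfg.af_recessive_max


def passes_af_filter(
    variant: VariantRecord,
    zygosity: Zygosity,
    inheritance: Inheritance | None,
    cfg: FilterConfig | None = None,
) -> bool:
    """Inheritance-aware allele-frequency gate.

    Unknown AF (absent from gnomAD) passes. When ``cfg.use_inhouse_af`` is
    set, the in-house cohort frequency must clear the same threshold.
    """
    cfg = cfg or FilterConfig()
    threshold = _af_threshold(zygosity, inheritance, cfg)
    if variant.gnomad_af is not None and variant.gnomad_af > threshold:
        return False
    if (
        cfg.use_inhouse_af
        and variant.inhouse_af is not None
        and variant.inhouse_af > threshold
    ):
        return False
    return True


def passes_acmg_filter(variant: VariantRecord, cfg: FilterConfig | None = None) -> bool:
    """True iff the ACMG class is in the retained set; unknown class fails."""
    cfg = cfg or FilterConfig()
    return variant.acmg_class is not None and variant.acmg_class in cfg.acmg_pass_classes


def is_splice_candidate(scores: SpliceScores, cfg: FilterConfig | None = None) -> bool:
    """True iff any of the four SpliceAI delta scores reaches the cutoff."""
    cfg = cfg or FilterConfig()
    return scores.max_score >= cfg.ds_min


def prioritise(
    proband: ProbandGenotype,
    genes: dict[str, GeneInfo],
    cfg: FilterConfig | None = None,
) -> ProbandGenotype:
    """Apply the full cascade to one proband; returns a filtered copy.

    The output variant set is always a subset of the input; flags record why
    each variant was retained. The cascade, in order:

    1. CNV records pass through unfiltered (``cnv_external``).
    2. Known pathogenic ABCA4 variants (config list, by ``gene:cdna`` key)
       are retained unconditionally (``known_abca4``).
    3. Known deep-intronic variants (config list) are extracted regardless of
       consequence (``known_div``).
    4. Remaining SNVs/indels pass iff both the AF and the ACMG gates pass.

    Splice candidates are flagged (``splice_candidate``) wherever SpliceAI
    scores are present, independent of retention route. A gene missing from
    the gene table triggers a warning; its variants are evaluated with
    unknown inheritance (recessive-context AF threshold).
    """
    cfg = cfg or FilterConfig()
    kept: list[tuple[VariantRecord, Zygosity]] = []
    flags: dict[str, frozenset[str]] = {}
    for variant, zygosity in proband.variants:
        info = genes.get(variant.gene)
        vflags: set[str] = set()
        if info is None:
            warnings.warn(
                f"gene {variant.gene} absent from gene table; "
                "evaluating with unknown inheritance",
                stacklevel=2,
            )
            vflags.add(FLAG_UNKNOWN_INHERITANCE)
        if variant.splice_scores is not None and is_splice_candidate(
            variant.splice_scores, cfg
        ):
            vflags.add(FLAG_SPLICE_CANDIDATE)

        if variant.consequence == "CNV":
            vflags.add(FLAG_CNV_EXTERNAL)
            retain = True
        elif variant.gene == "ABCA4" and variant.key in cfg.known_abca4_variants:
            vflags.add(FLAG_KNOWN_ABCA4)
            retain = True
        elif variant.key in cfg.known_div_variants:
            vflags.add(FLAG_KNOWN_DIV)
            retain = True
        else:
            inheritance = info.inheritance if info is not None else None
            retain = passes_af_filter(
                variant, zygosity, inheritance, cfg
            ) and passes_acmg_filter(variant, cfg)
        if retain:
            kept.append((variant, zygosity))
            # merge with pre-existing flags so the cascade is idempotent
            vflags |= set(proband.flags.get(variant.key, frozenset()))
            flags[variant.key] = frozenset(vflags)
    return ProbandGenotype(
        proband_id=proband.proband_id,
        phenotype=proband.phenotype,
        variants=kept,
        phase=dict(proband.phase),
        flags=flags,
        sex=proband.sex,
        qc_failed=proband.qc_failed,
    )
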