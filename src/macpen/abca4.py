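"""ABCA4 allele-severity grammar.

ABCA4-associated Stargardt disease behaves like a quantitative trait in the
amount of residual ABCA4 transporter activity: each allele carries a severity
category (no effect < mild < mild-moderately severe < moderately severe <
severe) and the genotype verdict depends on the combination of the two
allele severities. Variants in cis on one allele combine by taking the most
severe of the two categories (a join on the severity lattice). Mild alleles
are hypomorphic — pathogenic mainly opposite a more severe allele — and a
subset of mild alleles (canonically c.5882G>A; p.(Gly1961Glu)) additionally
shows reduced penetrance, which caps diagnostic confidence at
"possibly solved".

Splice-assay quantifications (percent wild-type RNA remaining) are mapped to
severity bands: the mild band is >40% and <80% WT RNA; the bands outside it
(no effect at >=80%, severe at <=40%) are extrapolations from the mild band's
endpoints and are reported as inferred classifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Phase, Severity, VerdictStatus

#: HGVS cDNA strings of mild ABCA4 alleles with documented reduced penetrance.
DEFAULT_REDUCED_PENETRANCE_MILD = frozenset({"c.5882G>A"})


@dataclass(frozen=True)
class SpliceAssayResult:
    """Quantified splice-assay outcome for one variant.

    pct_wt: percentage of wild-type RNA remaining (0-100).
    aberrant_products: (description, percentage) pairs; products contributing
        15% of total RNA or less are excluded from reporting.
    """

    variant: str
    pct_wt: float
    aberrant_products: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_wt <= 100.0):
            raise ValueError(f"pct_wt {self.pct_wt} outside [0, 100]")
        low = [d for d, p in self.aberrant_products if p <= 15.0]
        if low:
            raise ValueError(f"products at <=15% of total RNA must be excluded: {low}")


@dataclass(frozen=True)
class Abca4Config:
    """Severity assignments and reduced-penetrance list for known ABCA4 alleles."""

    severity_by_hgvs: dict = field(default_factory=dict)
    reduced_penetrance_mild: frozenset[str] = DEFAULT_REDUCED_PENETRANCE_MILD
    mild_band_low: float = 40.0
    mild_band_high: float = 80.0


def combine_cis_severity(sev_a: Severity, sev_b: Severity) -> Severity:
    """Severity of an allele carrying two variants in cis: the more severe one."""
    return max(sev_a, sev_b)


def classify_splice_result(
    pct_wt: float, cfg: Abca4Config | None = None
) -> tuple[Severity, bool]:
    """Map percent wild-type RNA to a severity band.

    Returns ``(severity, inferred)``: mild for the open band
    (mild_band_low, mild_band_high); outside it the classification is an
    inferred extrapolation (``inferred=True``) — no effect at or above the
    upper bound, severe at or below the lower bound. Boundary values fall in
    the inferred bands.
    """
    cfg = cfg or Abca4Config()
    if not (0.0 <= pct_wt <= 100.0):
        raise ValueError(f"pct_wt {pct_wt} outside [0, 100]")
    if cfg.mild_band_low < pct_wt < cfg.mild_band_high:
        return Severity.MILD, False
    if pct_wt >= cfg.mild_band_high:
        return Severity.NO_EFFECT, True
    return Severity.SEVERE, True


def abca4_genotype_verdict(
    allele_a: Severity,
    allele_b: Severity,
    phenotype: str = "",
    a_reduced_penetrance: bool = False,
    b_reduced_penetrance: bool = False,
    phase: Phase = Phase.PRESUMED_TRANS,
) -> tuple[VerdictStatus, str]:
    """Verdict contribution of a biallelic ABCA4 genotype (alleles in trans).

    Allele severities must already be cis-combined; a genotype whose two
    variants are in cis is a single allele and must not be passed here.
    Rules, symmetric in the two alleles:

    * any no-effect allele -> mono-allelic -> unsolved;
    * mild + mild -> unsolved (a mild allele needs a more severe partner);
    * reduced-penetrance mild (e.g. c.5882G>A) + an allele at least
      mild-moderately severe -> possibly solved (the reduced penetrance caps
      confidence; a STGD1 phenotype is recorded in the rule id);
    * otherwise (both alleles pathogenic, at most one plain mild) ->
      very likely solved.

    Returns the status and the identifier of the rule that fired.
    """
    if phase is Phase.CIS:
        raise ValueError(
            "alleles in cis must be combined with combine_cis_severity first"
        )
    # order so that (a) is the less severe allele; keep its penetrance flag
    (lo, lo_rp), (hi, _) = sorted(
        [(allele_a, a_reduced_penetrance), (allele_b, b_reduced_penetrance)],
        key=lambda t: t[0],
    )
    if lo is Severity.NO_EFFECT:
        return VerdictStatus.UNSOLVED, "abca4_mono_allelic"
    if lo is Severity.MILD and hi is Severity.MILD:
        return VerdictStatus.UNSOLVED, "abca4_mild_mild"
    if lo is Severity.MILD and lo_rp:
        rule = (
            "abca4_reduced_penetrance_mild_stgd1"
            if phenotype.upper().startswith("STGD")
            else "abca4_reduced_penetrance_mild"
        )
        return VerdictStatus.POSSIBLY_SOLVED, rule
    return VerdictStatus.VERY_LIKELY_SOLVED, "abca4_biallelic_pathogenic"
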