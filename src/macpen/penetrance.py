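"""Hardy-Weinberg penetrance estimation from a case-ascertained cohort.

For a genotype X (homozygous, compound heterozygous or hemizygous for given
variants), the penetrance is estimated by Bayes' rule:

    P(D | X) = P(X | D) * P(D) / P(X)

where P(X | D) is the genotype's frequency among probands, P(D) the disease
prevalence in the general population (default 1/5000 for inherited macular
dystrophies) and P(X) the genotype frequency expected under Hardy-Weinberg
equilibrium from population allele frequencies: q^2 for homozygotes,
2*q1*q2 for compound heterozygotes (no phase correction) and q for
hemizygotes. A penetrance well below 1 flags the variant as incompletely
penetrant; estimates above 1 are reported raw with a flag, because they
signal prevalence misspecification rather than a computable probability.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ProbandGenotype, Verdict

DEFAULT_PREVALENCE = 1.0 / 5000.0

#: Variants flagged in this cohort as having putative incomplete penetrance,
#: identified by gene:HGVS-cDNA key.
DEFAULT_REDUCED_PENETRANCE_VARIANTS = frozenset(
    {
        "ABCA4:c.5603A>T",
        "ABCA4:c.5882G>A",
        "ABCA4:c.4253+43G>A",
        "NMNAT1:c.769G>A",
        "PRPH2:c.424C>T",
        "PRPH2:c.514C>T",
        "PRPH2:c.623G>A",
        "RP1L1:c.133C>T",
        "CDHR1:c.783G>A",
        "CNGB3:c.1208G>A",
    }
)


class PenetranceFlag(str, enum.Enum):
    COMPLETE = "complete"
    REDUCED = "reduced"
    NOT_ESTIMABLE = "not_estimable"
    SUPRA_UNITY = "supra_unity"


@dataclass(frozen=True)
class GenotypeSpec:
    """A genotype class whose population frequency follows Hardy-Weinberg.

    kind: homozygous (q1^2), compound_het (2*q1*q2) or hemizygous (q1).
    """

    kind: str
    q1: float
    q2: float | None = None
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("homozygous", "compound_het", "hemizygous"):
            raise ValueError(f"unknown genotype kind {self.kind!r}")
        for q in (self.q1, self.q2):
            if q is not None and not (0.0 <= q <= 1.0):
                raise ValueError(f"allele frequency {q} outside [0, 1]")
        if self.kind == "compound_het":
            if self.q2 is None:
                raise ValueError("compound_het requires q2")
            if len(self.labels) >= 2 and self.labels[0] == self.labels[1]:
                raise ValueError("compound_het requires two distinct variants")


@dataclass
class PenetranceEstimate:
    genotype: GenotypeSpec | None
    observed_count: int
    cohort_n: int
    prevalence: float
    p_x: float
    p_x_given_d: float
    penetrance: float | None
    flag: PenetranceFlag

    @property
    def penetrance_pct(self) -> float | None:
        return None if self.penetrance is None else 100.0 * self.penetrance


def hw_genotype_frequency(spec: GenotypeSpec) -> float:
    """Expected population frequency of the genotype under Hardy-Weinberg."""
    if spec.kind == "homozygous":
        return spec.q1 * spec.q1
    if spec.kind == "compound_het":
        return 2.0 * spec.q1 * spec.q2
    return spec.q1  # hemizygous


def cohort_allele_frequency(allele_count: int, total_alleles: int) -> float:
    """Allele frequency within the cohort (diploid autosomal: 2n alleles)."""
    if total_alleles <= 0:
        raise ValueError("total_alleles must be positive")
    if total_alleles % 2 != 0:
        raise ValueError("total_alleles must be even for diploid autosomal loci")
    if not (0 <= allele_count <= total_alleles):
        raise ValueError("allele_count must be between 0 and total_alleles")
    return allele_count / total_alleles


def estimate_penetrance(
    observed_count: int,
    cohort_n: int,
    prevalence: float = DEFAULT_PREVALENCE,
    p_x: float | None = None,
    genotype: GenotypeSpec | None = None,
    reduced_threshold: float = 0.9,
) -> PenetranceEstimate:
    """Estimate P(D|X) = (observed/cohort_n) * prevalence / P(X).

    ``p_x`` may be given directly or derived from ``genotype``. Zero expected
    frequency or zero observations make the estimate not estimable; estimates
    above 1 are reported raw and flagged supra-unity.
    """
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    if not (0.0 < prevalence <= 1.0):
        raise ValueError("prevalence must be in (0, 1]")
    if observed_count < 0:
        raise ValueError("observed_count must be non-negative")
    if p_x is None:
        if genotype is None:
            raise ValueError("provide p_x or a genotype spec")
        p_x = hw_genotype_frequency(genotype)
    p_x_given_d = observed_count / cohort_n
    if p_x <= 0.0 or observed_count == 0:
        return PenetranceEstimate(
            genotype, observed_count, cohort_n, prevalence, p_x, p_x_given_d,
            None, PenetranceFlag.NOT_ESTIMABLE,
        )
    penetrance = p_x_given_d * prevalence / p_x
    if penetrance > 1.0:
        flag = PenetranceFlag.SUPRA_UNITY
    else:
        flag = flag_reduced_penetrance(penetrance, reduced_threshold)
    return PenetranceEstimate(
        genotype, observed_count, cohort_n, prevalence, p_x, p_x_given_d,
        penetrance, flag,
    )


def flag_reduced_penetrance(
    penetrance: float, threshold: float = 0.9
) -> PenetranceFlag:
    """Reduced iff the point estimate falls below the threshold (default 0.9)."""
    return (
        PenetranceFlag.REDUCED if penetrance < threshold else PenetranceFlag.COMPLETE
    )


def reduced_penetrance_census(
    verdicts: list[Verdict],
    genotypes: dict[str, ProbandGenotype],
    flagged_variants: frozenset[str] = DEFAULT_REDUCED_PENETRANCE_VARIANTS,
) -> tuple[int, float]:
    """Solved probands carrying at least one flagged reduced-penetrance variant.

    Returns ``(count, share_of_solved)``.
    """
    solved = [v for v in verdicts if v.solved]
    n_solved = len(solved)
    count = 0
    for v in solved:
        geno = genotypes.get(v.proband_id)
        if geno is None:
            continue
        if any(var.key in flagged_variants for var, _ in geno.variants):
            count += 1
    return count, (count / n_solved if n_solved else 0.0)


def prevalence_sweep(
    observed_count: int,
    cohort_n: int,
    p_x: float,
    prevalences: list[float] | None = None,
) -> pd.DataFrame:
    """Sensitivity of the estimate to the assumed disease prevalence.

    The estimator is linear in prevalence, so this is a transparency aid for
    reporting, not an inference procedure.
    """
    prevalences = prevalences or [1 / 2000, 1 / 5000, 1 / 10000, 1 / 20000, 1 / 40000]
    rows = []
    for p in prevalences:
        est = estimate_penetrance(observed_count, cohort_n, p, p_x)
        rows.append(
            {
                "prevalence": p,
                "penetrance": est.penetrance,
                "flag": est.flag.value,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_penetrance_ci(
    observed_count: int,
    cohort_n: int,
    prevalence: float,
    p_x: float,
    n_boot: int = 2000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the estimate (binomial resampling of the
    observed genotype count). A reporting convenience of this package, not a
    published procedure.
    """
    rng = np.random.default_rng(seed)
    counts = rng.binomial(cohort_n, observed_count / cohort_n, size=n_boot)
    estimates = counts / cohort_n * prevalence / p_x
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


#: Published inputs of the two incomplete-penetrance showcase variants:
#: gnomAD-ALL allele frequencies and observed genotype counts among the 1352
#: probands of the maculopathy cohort. The full cohort (not only the 1278
#: QC-passing probands) is the observation denominator, matching how the
#: genotype counts were reported; it is an argument, not a constant.
WORKED_EXAMPLE_INPUTS = [
    {
        "name": "CDHR1 c.783G>A homozygous",
        "genotype": GenotypeSpec("homozygous", q1=0.003052, labels=("CDHR1:c.783G>A",)),
        "observed_count": 13,
    },
    {
        "name": "CDHR1 c.783G>A / c.143C>A compound het",
        "genotype": GenotypeSpec(
            "compound_het",
            q1=0.003052,
            q2=0.000383,
            labels=("CDHR1:c.783G>A", "CDHR1:c.143C>A"),
        ),
        "observed_count": 2,
    },
    {
        "name": "CNGB3 c.1208G>A homozygous",
        "genotype": GenotypeSpec("homozygous", q1=0.004161, labels=("CNGB3:c.1208G>A",)),
        "observed_count": 4,
    },
]


def worked_examples(
    cohort_n: int = 1352, prevalence: float = DEFAULT_PREVALENCE
) -> list[PenetranceEstimate]:
    """Recompute the showcase incomplete-penetrance estimates from their inputs."""
    return [
        estimate_penetrance(
            observed_count=row["observed_count"],
            cohort_n=cohort_n,
            prevalence=prevalence,
            genotype=row["genotype"],
        )
        for row in WORKED_EXAMPLE_INPUTS
    ]


ESTIMATE_COLUMNS = [
    "kind",
    "variants",
    "q1",
    "q2",
    "observed_count",
    "cohort_n",
    "prevalence",
    "expected_hw_frequency",
    "observed_frequency",
    "penetrance",
    "flag",
]


def estimates_to_frame(estimates: list[PenetranceEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        g = e.genotype
        rows.append(
            {
                "kind": g.kind if g else "",
                "variants": ";".join(g.labels) if g else "",
                "q1": g.q1 if g else "",
                "q2": "" if g is None or g.q2 is None else g.q2,
                "observed_count": e.observed_count,
                "cohort_n": e.cohort_n,
                "prevalence": e.prevalence,
                "expected_hw_frequency": e.p_x,
                "observed_frequency": e.p_x_given_d,
                "penetrance": "" if e.penetrance is None else e.penetrance,
                "flag": e.flag.value,
            }
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
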