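"""Shared domain types for the maculopathy gene-panel pipeline.

The pipeline reasons about annotated variant calls from a targeted panel of
macular-dystrophy genes: each variant carries a population allele frequency
(gnomAD-ALL), an ACMG pathogenicity class (1 benign … 5 pathogenic, 3 = VUS),
a consequence category, optional SpliceAI delta scores and — for ABCA4 — an
optional allele-severity category reflecting residual protein activity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Severity(enum.IntEnum):
    """ABCA4 allele severity, ordered by decreasing residual protein activity.

    The integer order is the lattice order used when combining variants in
    cis: the combined allele takes the maximum severity.
    """

    NO_EFFECT = 0
    MILD = 1
    MILD_MODERATELY_SEVERE = 2
    MODERATELY_SEVERE = 3
    SEVERE = 4

    @classmethod
    def from_label(cls, label: str) -> "Severity":
        key = label.strip().lower().replace("-", "_").replace("/", "_").replace(" ", "_")
        aliases = {
            "benign": cls.NO_EFFECT,
            "benign_no_effect": cls.NO_EFFECT,
            "no_effect": cls.NO_EFFECT,
            "mild": cls.MILD,
            "mild_moderately_severe": cls.MILD_MODERATELY_SEVERE,
            "moderately_severe": cls.MODERATELY_SEVERE,
            "severe": cls.SEVERE,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown severity label: {label!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


class Phase(str, enum.Enum):
    CIS = "cis"
    TRANS = "trans"
    PRESUMED_TRANS = "presumed_trans"
    UNKNOWN = "unknown"


class Inheritance(str, enum.Enum):
    AR = "AR"
    AD = "AD"
    XL = "XL"
    MT = "MT"


class VerdictStatus(str, enum.Enum):
    VERY_LIKELY_SOLVED = "very_likely_solved"
    POSSIBLY_SOLVED = "possibly_solved"
    UNSOLVED = "unsolved"
    FAILED = "failed"


#: Closed consequence vocabulary of the panel's variant annotation.
CONSEQUENCES = frozenset(
    {
        "missense",
        "frameshift",
        "nonsense",
        "splice_altering",
        "CNV",
        "inframe_deletion",
        "inframe_insertion",
        "start_lost",
        "downstream",
        "utr5",
    }
)

#: Consequences expected to truncate the protein (used for the X-linked
#: female-carrier rule).
TRUNCATING_CONSEQUENCES = frozenset({"frameshift", "nonsense", "start_lost"})


@dataclass(frozen=True)
class SpliceScores:
    """SpliceAI delta scores for the four channels.

    ag/dg: acceptor/donor gain; al/dl: acceptor/donor loss. Each in [0, 1].
    """

    ag: float
    al: float
    dg: float
    dl: float

    def __post_init__(self) -> None:
        for name in ("ag", "al", "dg", "dl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"SpliceAI delta score {name}={v} outside [0, 1]")

    @property
    def max_score(self) -> float:
        return max(self.ag, self.al, self.dg, self.dl)


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele at one site.

    Coordinates are 1-based as in VCF. ``gnomad_af`` / ``acmg_class`` are
    ``None`` when the annotation is missing — a missing frequency means
    "absent from gnomAD", never 0.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    cdna: str = ""
    consequence: str = "missense"
    gnomad_af: float | None = None
    acmg_class: int | None = None
    splice_scores: SpliceScores | None = None
    abca4_severity: Severity | None = None
    in_silico_deleterious: bool = False
    inhouse_af: float | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"consequence {self.consequence!r} not in the closed vocabulary"
            )
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"gnomad_af {self.gnomad_af} outside [0, 1]")
        if self.acmg_class is not None and self.acmg_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"acmg_class {self.acmg_class} not in 1..5")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> str:
        """Stable identifier: gene plus HGVS cDNA if present, else coordinates."""
        if self.cdna:
            return f"{self.gene}:{self.cdna}"
        return f"{self.gene}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GeneInfo:
    gene: str
    inheritance: Inheritance
    associated_phenotypes: tuple[str, ...] = ()


@dataclass
class ProbandGenotype:
    """A proband's prioritised variants, with zygosity and per-gene phase."""

    proband_id: str
    phenotype: str = ""
    variants: list[tuple[VariantRecord, Zygosity]] = field(default_factory=list)
    #: per-gene phase of the (first) pair of heterozygous variants
    phase: dict[str, Phase] = field(default_factory=dict)
    #: per-variant-key flags set by the prioritisation cascade
    flags: dict[str, frozenset[str]] = field(default_factory=dict)
    sex: str | None = None
    qc_failed: bool = False

    def by_gene(self) -> dict[str, list[tuple[VariantRecord, Zygosity]]]:
        out: dict[str, list[tuple[VariantRecord, Zygosity]]] = {}
        for v, z in self.variants:
            out.setdefault(v.gene, []).append((v, z))
        return out


@dataclass
class Verdict:
    """Solved status for one proband with machine-readable rationale.

    ``rationale`` lists the identifiers of the rules that fired, so tests and
    auditors can see *why* a verdict was reached. ``causal_gene`` is set iff
    the status is very_likely_solved or possibly_solved.
    """

    proband_id: str
    status: VerdictStatus
    causal_gene: str | None = None
    rationale: list[str] = field(default_factory=list)
    candidate_genes: list[str] = field(default_factory=list)
    multi_gene: bool = False

    def __post_init__(self) -> None:
        solved = self.status in (
            VerdictStatus.VERY_LIKELY_SOLVED,
            VerdictStatus.POSSIBLY_SOLVED,
        )
        if solved and self.causal_gene is None:
            raise ValueError("solved verdict requires a causal gene")
        if not solved and self.causal_gene is not None:
            raise ValueError("unsolved/failed verdict must not carry a causal gene")

    @property
    def solved(self) -> bool:
        return self.status in (
            VerdictStatus.VERY_LIKELY_SOLVED,
            VerdictStatus.POSSIBLY_SOLVED,
        )
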