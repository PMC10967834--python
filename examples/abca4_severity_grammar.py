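"""The ABCA4 allele-severity grammar, from splice assay to genotype verdict.

ABCA4 alleles are graded by residual transporter activity (no effect < mild <
mild-moderately severe < moderately severe < severe). Splice-assay
quantifications map onto these grades; variants in cis combine by taking the
more severe grade; and the genotype verdict follows from the two allele
grades, with reduced-penetrance mild alleles (c.5882G>A) capping confidence
at "possibly solved".
"""

from macpen import Severity, combine_cis_severity
from macpen.abca4 import abca4_genotype_verdict, classify_splice_result

# splice-assay outcomes: percent wild-type RNA remaining
for variant, pct_wt in [("c.3329-124G>T", 45.0), ("c.1451A>G", 62.0),
                        ("c.6817-679C>G", 100.0)]:
    severity, inferred = classify_splice_result(pct_wt)
    note = " (inferred band)" if inferred else ""
    print(f"{variant}: {pct_wt:5.1f}% WT RNA -> {severity.label}{note}")

# two variants on one allele (in cis) combine to the more severe grade
combined = combine_cis_severity(Severity.MILD, Severity.MODERATELY_SEVERE)
print(f"\nmild + moderately_severe in cis -> {combined.label}")

# genotype verdicts for alleles in trans
cases = [
    ("mild (c.5882G>A) / moderately_severe, STGD1",
     (Severity.MILD, Severity.MODERATELY_SEVERE, "STGD1", True)),
    ("mild / severe", (Severity.MILD, Severity.SEVERE, "STGD1", False)),
    ("mild / mild", (Severity.MILD, Severity.MILD, "STGD1", False)),
    ("no_effect / severe", (Severity.NO_EFFECT, Severity.SEVERE, "STGD1", False)),
]
print()
for label, (a, b, phenotype, reduced) in cases:
    status, rule = abca4_genotype_verdict(a, b, phenotype, a_reduced_penetrance=reduced)
    print(f"{label}: {status.value}  [{rule}]")
# Only one pathogenic allele (or two plain mild alleles) leaves the genotype
# unsolved; a reduced-penetrance mild allele opposite a severe allele is
# reported as possibly solved rather than very likely solved.
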