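# Methods

This note documents the models and procedures implemented in `macpen`, the
assumptions behind them, the parameters that matter, and what the synthetic
data can and cannot establish about behaviour on real cohorts.

## Variant prioritisation

The cascade operates on annotated per-proband variant calls (VCF with
population allele frequency, ACMG class, consequence, optional SpliceAI
scores). In order:

1. **CNVs pass through** with a `cnv_external` flag: copy-number calling is
   delegated to a dedicated caller and its calls are consumed, not filtered.
2. **Known pathogenic ABCA4 variants** and **known deep-intronic variants**
   (both supplied as configuration lists keyed by `gene:HGVS-cDNA`) are
   extracted unconditionally, since frequency and class gates are designed
   for *novel* candidates and would wrongly drop, e.g., common hypomorphic
   ABCA4 alleles.
3. Remaining SNVs/indels must pass both gates:
   - **Allele frequency**, inheritance-aware: homozygous/hemizygous calls
     and heterozygous calls in recessive-gene context at minor AF ≤ 0.5%
     (`af_recessive_max = 0.005`); heterozygous calls in dominant-disease
     genes at ≤ 0.1% (`af_dominant_het_max = 0.001`). A variant absent from
     gnomAD passes: absence of a frequency annotation means the variant is
     rare, never that its frequency is zero by assertion — coercing missing
     to 0 would silently promote annotation failures.
   - **ACMG class** in {3, 4, 5}. An unknown class fails the gate
     (conservative: only classified variants are prioritised).
4. Variants with any SpliceAI delta score ≥ 0.2 (`ds_min`) are flagged
   `splice_candidate` regardless of retention route.

Heterozygous variants in X-linked genes (female carriers) are evaluated
under the dominant-gene threshold by default
(`xl_het_uses_dominant_threshold = True`); hemizygous calls always use the
recessive threshold. An optional in-house-cohort frequency annotation can be
enabled as a second gate with the same thresholds (`use_inhouse_af`,
off by default). A gene absent from the inheritance table triggers a warning
and is evaluated with unknown inheritance (recessive-context threshold).

The cascade is a pure filter: its output is always a subset of its input,
it is idempotent, and raising a frequency ceiling can only add variants.
These properties, plus equivalence with a brute-force gate enumeration, are
asserted by property-based tests.

## ABCA4 severity grammar

ABCA4-associated disease severity tracks residual transporter activity, so
alleles carry an ordered severity grade: `no_effect < mild <
mild_moderately_severe < moderately_severe < severe`. Implementation
decisions:

- **Cis combination** is the lattice join (maximum) of the two grades —
  commutative, associative, idempotent.
- **Splice-assay banding**: the mild band is the open interval 40% < %WT RNA
  < 80%. The bands outside it are not independently established; the
  implementation extrapolates from the mild band's endpoints (≥ 80% → no
  effect, ≤ 40% → severe), returns an `inferred=True` marker for them, and
  exposes both boundaries as configuration. Values exactly at 40 or 80 fall
  in the inferred bands (tests pin this; the intent at the exact boundary is
  not established by the assay data, so the choice is explicit rather than
  guessed-and-hidden).
- **Genotype verdicts** (alleles in trans; cis pairs must be combined
  first): any `no_effect` allele leaves the genotype mono-allelic →
  unsolved; mild/mild → unsolved (a mild hypomorphic allele is pathogenic
  mainly opposite a more severe allele); a *reduced-penetrance* mild allele
  (configured list, canonically c.5882G>A) opposite an allele graded at
  least mild-moderately severe → possibly solved; all remaining biallelic
  pathogenic combinations → very likely solved.

  The reduced-penetrance rule is stated in the source material only for a
  STGD1 phenotype. This implementation applies the possibly-solved cap for
  any phenotype and records whether the phenotype was STGD1 in the fired
  rule identifier, on the reasoning that reduced penetrance weakens causal
  confidence regardless of the presenting phenotype; restricting the cap to
  STGD1 would *upgrade* confidence exactly where genotype and phenotype
  agree least.

## Verdict engine

Each gene with retained variants is evaluated under its inheritance mode;
the proband's verdict is the best per-gene contribution (very likely >
possibly > unsolved), with rule identifiers recording every contribution:

- **AR**: biallelic class-4/5 (homozygous, or two distinct heterozygous
  variants in trans or presumed trans) → very likely solved; biallelic
  combinations involving a class-3 VUS → possibly solved.
- **ABCA4** genotypes are routed through the severity grammar whenever both
  allele severities are known (from annotation or the severity table);
  otherwise they fall back to the generic recessive rules.
- **AD**: heterozygous class-4/5 → very likely solved; heterozygous VUS with
  deleterious in-silico support → possibly solved.
- **XL**: hemizygous (or homozygous female) class-4/5 → very likely solved;
  heterozygous truncating class-4/5 in a female → possibly solved (carrier
  manifestation).
- **MT**: a class-4/5 mitochondrial variant → very likely solved, with a
  rule id marking that heteroplasmy review is pending.
- A gene missing from the inheritance table contributes at most possibly
  solved (biallelic class-4/5), since the mode of inheritance is
  unverifiable.

**Phase**: without segregation or long-read evidence, two distinct rare
heterozygous variants in one gene are presumed in trans
(`presumed_trans`); supplied experimental phase always overrides. This
presumption is the single largest caveat on recessive verdicts and is why
the verdict carries the rule id rather than silently asserting phase.

**Multi-gene probands**: when class-4/5 genotypes exist in more than one
gene, all candidates are reported and the verdict is flagged `multi_gene`.
Selecting the primary gene requires phenotype adjudication by a clinician,
which is not computable from the stated rules; the engine accepts an
external primary-gene override and otherwise breaks ties deterministically
(best status, then alphabetical).

**Summaries**: diagnostic yield = solved / (sequenced − failed). Shares are
printed as percentages rounded half-up to one decimal, the convention used
in diagnostic reporting. QC-failed probands receive a `failed` verdict and
leave the yield denominator.

Carrier censuses count probands harbouring at least one *heterozygous*
class-4/5 variant in a recessive gene, or a severity-graded ABCA4 variant,
outside their own causal gene; ABCA4 c.2588G>C is excluded by default
because it is benign when not in cis with c.5603A>T.

## Penetrance estimation

`P(D|X) = P(X|D)·P(D)/P(X)` with `P(X)` from Hardy–Weinberg (homozygote
`q²`, compound heterozygote `2q₁q₂` with no phase correction, hemizygote
`q`). Parameters:

- **Prevalence** `P(D)`: default 1/5000 for inherited macular dystrophies
  as a class. The estimate is linear in prevalence, and prevalence is the
  least certain input, so `prevalence_sweep` reports the estimate across a
  grid rather than pretending to a single truth. If a variant is specific to
  a disease subtype, using the class-wide prevalence overestimates `P(D)`
  and hence the estimate is an upper bound on subtype penetrance.
- **Cohort denominator**: the estimator takes the observation denominator as
  an argument. Genotype counts reported against all recruited probands use
  the full cohort size (e.g. 1352) even when some probands failed
  sequencing QC (1278 passing); the two conventions differ by ~5% and the
  choice is the caller's, not hidden in the code.
- **Flags**: `reduced` below a 0.9 threshold (configurable), `not_estimable`
  for zero expected frequency or zero observations, `supra_unity` for
  estimates above 1 — reported raw, never clamped, because they diagnose
  prevalence misspecification or ancestry-skewed allele frequencies.
- A percentile bootstrap CI on the observed genotype count (binomial
  resampling, seeded) is available as a reporting convenience of this
  package.

Known limitations, acknowledged and not modelled: global allele frequencies
ignore ancestry structure (a variant concentrated in one population makes
the Hardy–Weinberg homozygote frequency an underestimate and the penetrance
an overestimate); no linkage disequilibrium; no genetic modifiers.

## mtDNA heteroplasmy

Heteroplasmy is `alt/(ref+alt)` from allele depths. Two thresholds:

- `min_depth = 100` for a reliable call — a floor chosen by this package
  (no published floor exists for the assay); shallower calls report the
  fraction but are marked unreliable.
- `caller_floor = 0.16`: germline callers in the validation experiment
  failed to report variants below ~16% heteroplasmy. The floor models that
  observed behaviour as a post-hoc detectability threshold — it is not a
  reimplementation of any caller. Sub-floor calls are flagged for manual
  review of read alignments rather than dropped, since a 6% control was
  recoverable manually.

**Lin's concordance correlation coefficient** quantifies agreement with
known control levels: `ρc = 2·s_xy / (s_x² + s_y² + (x̄−ȳ)²)` with
population (1/n) moments, per Lin's original formulation — sample-moment
variants differ noticeably at n = 13. The 95% CI uses the Fisher
z-transform with Lin's asymptotic standard error. Degenerate inputs are
defined explicitly: two identical constant vectors → ρc = 1; two constant
vectors with different values → ρc = 0; fewer than 3 pairs → error. The
implementation is cross-checked in tests against an independently coded
direct-formula oracle to 1e-12 and against the inequality |ρc| ≤ |r|.

NUMT contamination (nuclear sequences of mitochondrial origin) and
tissue-level heteroplasmy differences (blood vs retina) are out of scope; a
module-level caveat documents both.

## Coverage QC

Mapped reads = (forward + reverse)/2, exact arithmetic with half-up rounding
to integer. Per-nucleotide coverage = average per-smMIP coverage × smMIPs
per nucleotide (8 in this panel design; 85× average probe coverage hence
680× per nucleotide). The QC rule — fail below 10× average per-smMIP
coverage — is this package's stand-in: the real failure criterion (upstream
DNA quality) is not computable from read counts, and the floor is
configurable.

## Synthetic cohorts

The generator emulates exactly the generative structure the estimator
assumes: genotypes drawn independently per variant under Hardy–Weinberg
proportions; disease Bernoulli with the penetrance of the individual's
highest-priority causal genotype; non-causal individuals affected at a
phenocopy background rate solved to make the realised prevalence match the
target (reflecting that a majority of real probands are unexplained by the
panel); probands sampled uniformly from cases. One global seed; each stage
derives its generator by `SeedSequence` spawning, making every artefact
(including the emitted VCF) byte-reproducible.

For estimator-calibration studies the package also provides an aggregated
replication path (`replicate_homozygote_counts`): multinomial genotype-class
counts → binomial disease per class → multivariate-hypergeometric
ascertainment. Because individuals within a genotype class are
exchangeable, this is an *exact* aggregation of the individual-level model,
not an approximation; a test checks the two paths agree distributionally.
It runs in O(1) per replicate, so the calibration study (200 replicates per
penetrance level at population 2×10⁷, cohort 1352) takes well under a
second. Problem sizes used elsewhere in the suite (populations of 10⁵–4×10⁵
for individual-level checks) were chosen to make binomial standard errors
small relative to the tested effects.

What the synthetic data does **not** contain: linkage disequilibrium and
complex alleles (a cis complex allele can be emulated as one composite
variant), ancestry structure, annotation errors, capture bias, or read-level
artefacts. Passing tests therefore establish the *logic* of the pipeline
and the *statistical calibration* of the estimator under its own
assumptions — not robustness to real-data annotation noise or population
structure.

## Numerical conventions

- Percentages in summaries: round half-up at one decimal (two where noted),
  via exact `Decimal` arithmetic.
- Threshold gates are inclusive (AF ≤ cutoff passes; DS ≥ cutoff flags;
  heteroplasmy ≥ floor is caller-detectable).
- Verdict tie-breaks are deterministic (status rank, then alphabetical
  gene), so identical inputs always produce identical outputs.
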