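"""Generate a synthetic case-ascertained cohort and recover a known penetrance.

The generator draws a population under Hardy-Weinberg, assigns disease with
genotype-specific penetrance plus a phenocopy background filling the target
prevalence, and samples probands from cases only. Running the estimator on
replicated cohorts shows it recovers the true penetrance without bias — the
calibration argument behind trusting its output on real cohorts.
"""

import numpy as np

from macpen.model import Inheritance
from macpen.simulate import (
    PenetranceRule,
    SimulationConfig,
    SimVariant,
    recover_homozygote_penetrance,
    simulate_cohort,
)

# one small cohort, end to end, written as VCF + TSVs
cfg = SimulationConfig(
    seed=5,
    n_population=100_000,
    variants=[SimVariant("CDHR1", "c.783G>A", af=0.02, acmg_class=5,
                         consequence="splice_altering", inheritance=Inheritance.AR)],
    penetrance_rules=[PenetranceRule("CDHR1", "homozygous", penetrance=0.5)],
    prevalence_target=0.01,
    n_probands=300,
)
population, disease, cohort, paths = simulate_cohort(cfg, "scratch/sim_demo")
hom = (cohort["CDHR1:c.783G>A"] == 2).sum()
print(f"population: {len(population):,}, cases: {int(disease.sum()):,}, "
      f"ascertained probands: {len(cohort)} ({hom} homozygous)")
print(f"files written: {sorted(p.name for p in paths.values())}")

# replicated recovery in the regime of the real cohort: rare allele
# (q = 0.3052%), 1352 probands, assumed prevalence 1/5000
true_pi = 0.207
estimates = recover_homozygote_penetrance(
    q=0.003052, true_penetrance=true_pi, prevalence=1 / 5000,
    n_probands=1352, n_population=20_000_000, n_replicates=200, seed=42,
)
se = estimates.std(ddof=1) / np.sqrt(len(estimates))
print(f"\ntrue penetrance {true_pi:.3f}; estimator mean over 200 cohorts "
      f"{estimates.mean():.3f} +/- {se:.3f} (Monte-Carlo SE)")
# The mean tracking the truth within Monte-Carlo error is what licenses the
# Bayes-rule estimator under case ascertainment at the assumed prevalence.
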