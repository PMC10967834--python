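"""Hardy-Weinberg penetrance estimator: worked values, algebra, censuses."""

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_proband, make_variant

from macpen.model import Verdict, VerdictStatus, Zygosity
from macpen.penetrance import (
    DEFAULT_REDUCED_PENETRANCE_VARIANTS,
    GenotypeSpec,
    PenetranceFlag,
    cohort_allele_frequency,
    estimate_penetrance,
    flag_reduced_penetrance,
    hw_genotype_frequency,
    reduced_penetrance_census,
    worked_examples,
)


class TestHardyWeinbergFrequency:
    def test_homozygote_frequency_cdhr1_regime(self):
        # q = 0.3052% -> homozygote frequency 0.000931%
        spec = GenotypeSpec("homozygous", q1=0.003052)
        assert hw_genotype_frequency(spec) * 100 == pytest.approx(0.000931, abs=5e-7)

    def test_compound_het_frequency(self):
        # q1 = 0.3052%, q2 = 0.0383% -> 2*q1*q2 = 0.000234%
        spec = GenotypeSpec("compound_het", q1=0.003052, q2=0.000383)
        assert hw_genotype_frequency(spec) * 100 == pytest.approx(0.000234, abs=5e-7)

    def test_cngb3_homozygote_frequency(self):
        spec = GenotypeSpec("homozygous", q1=0.004161)
        assert hw_genotype_frequency(spec) * 100 == pytest.approx(0.001731, abs=5e-7)

    def test_hemizygous_frequency_is_allele_frequency(self):
        assert hw_genotype_frequency(GenotypeSpec("hemizygous", q1=0.01)) == 0.01

    def test_zero_frequency_allele(self):
        assert hw_genotype_frequency(GenotypeSpec("homozygous", q1=0.0)) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        q1=st.floats(0, 1, allow_nan=False),
        q2=st.floats(0, 1, allow_nan=False),
        dq=st.floats(0, 0.5, allow_nan=False),
    )
    def test_monotone_in_each_allele_frequency(self, q1, q2, dq):
        hom = GenotypeSpec("homozygous", q1=q1)
        assert hw_genotype_frequency(hom) <= q1  # q^2 <= q on [0,1]
        bumped = GenotypeSpec("homozygous", q1=min(1.0, q1 + dq))
        assert hw_genotype_frequency(bumped) >= hw_genotype_frequency(hom)
        chet = GenotypeSpec("compound_het", q1=q1, q2=q2, labels=("a", "b"))
        chet_b = GenotypeSpec(
            "compound_het", q1=min(1.0, q1 + dq), q2=q2, labels=("a", "b")
        )
        assert hw_genotype_frequency(chet_b) >= hw_genotype_frequency(chet)

    def test_validation(self):
        with pytest.raises(ValueError):
            GenotypeSpec("homozygous", q1=1.2)
        with pytest.raises(ValueError):
            GenotypeSpec("compound_het", q1=0.1)  # missing q2
        with pytest.raises(ValueError):
            GenotypeSpec("compound_het", q1=0.1, q2=0.1, labels=("a", "a"))


class TestEstimator:
    def test_cngb3_homozygote_penetrance(self):
        est = estimate_penetrance(4, 1352, 1 / 5000, 1.731392e-5)
        assert est.penetrance_pct == pytest.approx(3.4, abs=0.05)
        assert est.flag is PenetranceFlag.REDUCED

    def test_cdhr1_homozygote_penetrance_within_print_tolerance(self):
        est = estimate_penetrance(13, 1352, 1 / 5000, 0.003052**2)
        assert est.penetrance_pct == pytest.approx(20.7, abs=0.1)

    def test_cdhr1_compound_het_penetrance_within_print_tolerance(self):
        est = estimate_penetrance(2, 1352, 1 / 5000, 2 * 0.003052 * 0.000383)
        assert est.penetrance_pct == pytest.approx(12.6, abs=0.1)

    def test_formula_identity_gives_unity(self):
        # k/n = p_x / prevalence  =>  penetrance exactly 1
        est = estimate_penetrance(5, 1000, 0.01, 5 / 1000 * 0.01)
        assert est.penetrance == pytest.approx(1.0)
        assert est.flag is PenetranceFlag.COMPLETE

    @settings(deadline=None, derandomize=True)
    @given(
        k=st.integers(1, 50),
        n=st.integers(100, 5000),
        prev=st.floats(1e-6, 1e-2, allow_nan=False),
        p_x=st.floats(1e-9, 1e-3, allow_nan=False),
    )
    def test_linearity_and_scaling(self, k, n, prev, p_x):
        base = estimate_penetrance(k, n, prev, p_x).penetrance
        assert estimate_penetrance(k, n, 2 * prev, p_x).penetrance == pytest.approx(
            2 * base, rel=1e-12
        )
        assert estimate_penetrance(k, n, prev, p_x / 2).penetrance == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_not_estimable_and_supra_unity_flags(self):
        assert (
            estimate_penetrance(0, 100, 1 / 5000, 1e-6).flag
            is PenetranceFlag.NOT_ESTIMABLE
        )
        assert (
            estimate_penetrance(5, 100, 1 / 5000, 0.0).flag
            is PenetranceFlag.NOT_ESTIMABLE
        )
        supra = estimate_penetrance(50, 100, 0.01, 1e-6)
        assert supra.flag is PenetranceFlag.SUPRA_UNITY
        assert supra.penetrance > 1.0  # reported raw, not clamped

    def test_validation(self):
        with pytest.raises(ValueError):
            estimate_penetrance(1, 0, 1 / 5000, 1e-6)
        with pytest.raises(ValueError):
            estimate_penetrance(1, 100, 0.0, 1e-6)

    def test_reduced_flagging_threshold(self):
        assert flag_reduced_penetrance(0.034) is PenetranceFlag.REDUCED
        assert flag_reduced_penetrance(0.207) is PenetranceFlag.REDUCED
        assert flag_reduced_penetrance(1.0) is PenetranceFlag.COMPLETE
        assert flag_reduced_penetrance(0.5, threshold=0.4) is PenetranceFlag.COMPLETE


def test_worked_examples_bundle():
    ests = worked_examples()
    assert [e.flag for e in ests] == [PenetranceFlag.REDUCED] * 3
    assert ests[0].penetrance_pct == pytest.approx(20.7, abs=0.1)
    assert ests[1].penetrance_pct == pytest.approx(12.6, abs=0.1)
    assert ests[2].penetrance_pct == pytest.approx(3.4, abs=0.05)


class TestCohortAlleleFrequency:
    def test_reported_example(self):
        af = cohort_allele_frequency(31, 2704)
        assert round(af * 100, 2) == 1.15

    def test_zero_count(self):
        assert cohort_allele_frequency(0, 2704) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(k=st.integers(0, 4000), n=st.integers(1, 2000))
    def test_matches_exact_rational_arithmetic(self, k, n):
        total = 2 * n
        k = min(k, total)
        assert cohort_allele_frequency(k, total) == pytest.approx(
            float(Fraction(k, total)), rel=1e-15
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            cohort_allele_frequency(1, 0)
        with pytest.raises(ValueError):
            cohort_allele_frequency(1, 3)  # odd allele total
        with pytest.raises(ValueError):
            cohort_allele_frequency(5, 4)


class TestReducedPenetranceCensus:
    @staticmethod
    def _cohort(rng):
        flagged = sorted(DEFAULT_REDUCED_PENETRANCE_VARIANTS)
        verdicts, genotypes = [], {}
        for i in range(150):
            pid = f"P{i:04d}"
            calls = []
            for j in range(rng.randint(0, 3)):
                if rng.random() < 0.3:
                    gene, cdna = rng.choice(flagged).split(":")
                else:
                    gene, cdna = "ABCA4", f"c.{j + 1}T>C"
                calls.append(
                    (
                        make_variant(gene=gene, cdna=cdna, pos=10 * (j + 1)),
                        rng.choice([Zygosity.HET, Zygosity.HOM]),
                    )
                )
            genotypes[pid] = make_proband(pid=pid, variants=calls)
            solved = rng.random() < 0.4
            verdicts.append(
                Verdict(
                    proband_id=pid,
                    status=(
                        VerdictStatus.VERY_LIKELY_SOLVED
                        if solved
                        else VerdictStatus.UNSOLVED
                    ),
                    causal_gene="ABCA4" if solved else None,
                    rationale=["r"],
                )
            )
        return verdicts, genotypes

    def test_matches_bruteforce_membership_count(self):
        rng = random.Random(17)
        verdicts, genotypes = self._cohort(rng)
        count, share = reduced_penetrance_census(verdicts, genotypes)
        expected = sum(
            1
            for v in verdicts
            if v.solved
            and any(
                var.key in DEFAULT_REDUCED_PENETRANCE_VARIANTS
                for var, _ in genotypes[v.proband_id].variants
            )
        )
        n_solved = sum(1 for v in verdicts if v.solved)
        assert count == expected
        assert share == pytest.approx(expected / n_solved)

    def test_empty_flagged_list_counts_nothing(self):
        rng = random.Random(17)
        verdicts, genotypes = self._cohort(rng)
        assert reduced_penetrance_census(verdicts, genotypes, frozenset()) == (0, 0.0)

    def test_reported_share_regime(self):
        # 143 of 508 solved probands carrying a flagged variant -> 28.1%
        verdicts, genotypes = [], {}
        flagged_variant = make_variant(gene="CDHR1", cdna="c.783G>A")
        plain = make_variant(gene="ABCA4", cdna="c.1T>C")
        for i in range(508):
            pid = f"S{i:04d}"
            v = flagged_variant if i < 143 else plain
            genotypes[pid] = make_proband(pid=pid, variants=[(v, Zygosity.HOM)])
            verdicts.append(
                Verdict(
                    proband_id=pid,
                    status=VerdictStatus.VERY_LIKELY_SOLVED,
                    causal_gene=v.gene,
                    rationale=["r"],
                )
            )
        count, share = reduced_penetrance_census(verdicts, genotypes)
        assert count == 143
        assert round(share * 100, 1) == 28.1
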