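"""Verdict engine: phase presumption, rule table, cohort summaries, censuses."""

import itertools
import random

import pytest

from conftest import make_proband, make_variant

from macpen.abca4 import Abca4Config
from macpen.model import (
    GeneInfo,
    Inheritance,
    Phase,
    Severity,
    VerdictStatus,
    Zygosity,
)
from macpen.verdicts import (
    assign_verdict,
    carrier_census,
    cohort_summary,
    presume_phase,
    round_half_up_pct,
)


def test_presumed_trans_for_two_distinct_hets():
    a = make_variant(gene="ROM1", cdna="c.339dupG", consequence="frameshift")
    b = make_variant(gene="ROM1", cdna="c.712del", consequence="frameshift")
    assert presume_phase([(a, Zygosity.HET), (b, Zygosity.HET)]) is Phase.PRESUMED_TRANS


def test_experimental_phase_overrides_presumption():
    a = make_variant(gene="ROM1", cdna="c.339dupG", consequence="frameshift")
    b = make_variant(gene="ROM1", cdna="c.712del", consequence="frameshift")
    calls = [(a, Zygosity.HET), (b, Zygosity.HET)]
    assert presume_phase(calls, evidence=Phase.TRANS) is Phase.TRANS
    assert presume_phase(calls, evidence=Phase.CIS) is Phase.CIS


def test_single_homozygote_has_no_phase():
    v = make_variant(gene="RP1L1", cdna="c.1509del", consequence="frameshift")
    assert presume_phase([(v, Zygosity.HOM)]) is Phase.UNKNOWN


def test_homozygous_frameshift_in_recessive_gene_solves(gene_table):
    v = make_variant(
        gene="RP1L1", cdna="c.1509del", consequence="frameshift",
        gnomad_af=None, acmg_class=5,
    )
    verdict = assign_verdict(make_proband(variants=[(v, Zygosity.HOM)]), gene_table)
    assert verdict.status is VerdictStatus.VERY_LIKELY_SOLVED
    assert verdict.causal_gene == "RP1L1"
    assert "RP1L1:ar_biallelic_class45" in verdict.rationale


def test_xl_female_heterozygous_truncating_is_possibly_solved(gene_table):
    v = make_variant(
        gene="CACNA1F", cdna="c.1566_1575del", consequence="frameshift",
        gnomad_af=None, acmg_class=4,
    )
    verdict = assign_verdict(
        make_proband(variants=[(v, Zygosity.HET)], sex="F"), gene_table
    )
    assert verdict.status is VerdictStatus.POSSIBLY_SOLVED
    assert verdict.causal_gene == "CACNA1F"


def test_ad_missense_vus_with_insilico_support_is_possibly_solved(gene_table):
    v = make_variant(
        gene="PRPH2", cdna="c.999A>T", gnomad_af=1e-5, acmg_class=3,
        in_silico_deleterious=True,
    )
    verdict = assign_verdict(make_proband(variants=[(v, Zygosity.HET)]), gene_table)
    assert verdict.status is VerdictStatus.POSSIBLY_SOLVED


def test_qc_failed_proband_gets_failed_verdict(gene_table):
    verdict = assign_verdict(make_proband(qc_failed=True), gene_table)
    assert verdict.status is VerdictStatus.FAILED
    assert verdict.causal_gene is None


def test_abca4_genotypes_are_routed_through_severity_grammar(gene_table):
    mild = make_variant(
        gene="ABCA4", cdna="c.5882G>A", gnomad_af=0.004, acmg_class=5,
        abca4_severity=Severity.MILD, pos=10,
    )
    msev = make_variant(
        gene="ABCA4", cdna="c.768G>T", gnomad_af=1e-4, acmg_class=5,
        abca4_severity=Severity.MODERATELY_SEVERE, pos=20,
    )
    proband = make_proband(
        phenotype="STGD1", variants=[(mild, Zygosity.HET), (msev, Zygosity.HET)]
    )
    verdict = assign_verdict(proband, gene_table, Abca4Config())
    assert verdict.status is VerdictStatus.POSSIBLY_SOLVED
    assert "ABCA4:abca4_reduced_penetrance_mild_stgd1" in verdict.rationale


def test_multi_gene_class45_genotypes_are_flagged_and_overridable(gene_table):
    rp1l1 = make_variant(gene="RP1L1", cdna="c.1509del", consequence="frameshift",
                         gnomad_af=None, acmg_class=5, pos=10)
    cdhr1 = make_variant(gene="CDHR1", cdna="c.783G>A", gnomad_af=0.003052,
                         acmg_class=5, pos=20)
    proband = make_proband(variants=[(rp1l1, Zygosity.HOM), (cdhr1, Zygosity.HOM)])
    verdict = assign_verdict(proband, gene_table)
    assert verdict.multi_gene
    assert set(verdict.candidate_genes) == {"RP1L1", "CDHR1"}
    assert verdict.causal_gene == "CDHR1"  # alphabetical tie-break
    overridden = assign_verdict(proband, gene_table, primary_gene_override="RP1L1")
    assert overridden.causal_gene == "RP1L1"


# ---------------------------------------------------------------------------
# Rule-table equivalence with an independent enumeration oracle
# ---------------------------------------------------------------------------

MODE_GENE = {"AR": "CDHR1", "AD": "PRPH2", "XL": "CACNA1F", "MT": "MT-TL1"}


def oracle_single_gene(mode, config):
    """Hand-enumerated expected status for one gene's genotype configuration."""
    kind = config[0]
    if mode == "MT":
        classes = [c for c in config[1:] if isinstance(c, int)]
        return "VLS" if any(c in (4, 5) for c in classes) else None
    if kind == "hom":
        c = config[1]
        if mode == "AR":
            return "VLS" if c in (4, 5) else ("PS" if c == 3 else None)
        if mode == "AD":
            return "VLS" if c in (4, 5) else None
        if mode == "XL":
            return "VLS" if c in (4, 5) else None
    if kind == "hemi":
        c = config[1]
        return "VLS" if mode == "XL" and c in (4, 5) else None
    if kind == "het":
        c, insilico, truncating = config[1:]
        if mode == "AD":
            if c in (4, 5):
                return "VLS"
            return "PS" if c == 3 and insilico else None
        if mode == "XL":
            return "PS" if c in (4, 5) and truncating else None
        return None
    if kind == "two_het":
        c1, c2, phase = config[1:]
        if mode == "AD":
            return "VLS" if c1 in (4, 5) or c2 in (4, 5) else None
        if mode == "AR" and phase is Phase.PRESUMED_TRANS:
            if c1 in (4, 5) and c2 in (4, 5):
                return "VLS"
            if c1 in (3, 4, 5) and c2 in (3, 4, 5):
                return "PS"
        return None
    return None


def enumerate_configs():
    classes = (2, 3, 4, 5)
    for c in classes:
        yield ("hom", c)
        yield ("hemi", c)
        for insilico in (False, True):
            for truncating in (False, True):
                yield ("het", c, insilico, truncating)
    for c1, c2 in itertools.product(classes, classes):
        for phase in (Phase.PRESUMED_TRANS, Phase.CIS):
            yield ("two_het", c1, c2, phase)


def build_proband(mode, config):
    gene = MODE_GENE[mode]
    kind = config[0]
    if kind in ("hom", "hemi"):
        v = make_variant(gene=gene, cdna="c.1A>G", gnomad_af=1e-4, acmg_class=config[1])
        zyg = Zygosity.HOM if kind == "hom" else Zygosity.HEMI
        return make_proband(variants=[(v, zyg)])
    if kind == "het":
        c, insilico, truncating = config[1:]
        v = make_variant(
            gene=gene, cdna="c.1A>G", gnomad_af=1e-4, acmg_class=c,
            consequence="frameshift" if truncating else "missense",
            in_silico_deleterious=insilico,
        )
        return make_proband(variants=[(v, Zygosity.HET)])
    c1, c2, phase = config[1:]
    a = make_variant(gene=gene, cdna="c.1A>G", gnomad_af=1e-4, acmg_class=c1, pos=10)
    b = make_variant(gene=gene, cdna="c.2C>T", gnomad_af=1e-4, acmg_class=c2, pos=20)
    return make_proband(
        variants=[(a, Zygosity.HET), (b, Zygosity.HET)],
        phase={gene: phase},
    )


def test_rule_table_matches_enumeration_oracle(gene_table):
    expected_map = {
        "VLS": VerdictStatus.VERY_LIKELY_SOLVED,
        "PS": VerdictStatus.POSSIBLY_SOLVED,
        None: VerdictStatus.UNSOLVED,
    }
    n_checked = 0
    for mode in MODE_GENE:
        for config in enumerate_configs():
            proband = build_proband(mode, config)
            verdict = assign_verdict(proband, gene_table)
            expected = expected_map[oracle_single_gene(mode, config)]
            assert verdict.status is expected, (mode, config, verdict.rationale)
            n_checked += 1
    assert n_checked == 4 * len(list(enumerate_configs()))


def test_every_proband_gets_exactly_one_status(gene_table):
    rng = random.Random(11)
    statuses = []
    for i in range(60):
        mode = rng.choice(list(MODE_GENE))
        config = rng.choice(list(enumerate_configs()))
        proband = build_proband(mode, config)
        proband.qc_failed = rng.random() < 0.1
        statuses.append(assign_verdict(proband, gene_table).status)
    counts = {s: statuses.count(s) for s in VerdictStatus}
    assert sum(counts.values()) == 60


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


def _synthetic_verdict(i, status, gene=None):
    from macpen.model import Verdict

    return Verdict(
        proband_id=f"P{i:05d}",
        status=status,
        causal_gene=gene,
        rationale=["r"],
        candidate_genes=[gene] if gene else [],
    )


def test_cohort_summary_reproduces_reported_shares(gene_table):
    # 1352 sequenced, 74 failed, 508 solved: 379 AR / 105 AD / 18 XL / 6 MT
    verdicts = []
    i = 0
    for _ in range(74):
        verdicts.append(_synthetic_verdict(i, VerdictStatus.FAILED)); i += 1
    for gene, n in (("CDHR1", 379), ("PRPH2", 105), ("CACNA1F", 18), ("MT-TL1", 6)):
        for _ in range(n):
            verdicts.append(
                _synthetic_verdict(i, VerdictStatus.VERY_LIKELY_SOLVED, gene)
            ); i += 1
    while i < 1352:
        verdicts.append(_synthetic_verdict(i, VerdictStatus.UNSOLVED)); i += 1

    summary = cohort_summary(verdicts, genes=gene_table)
    assert summary.n_sequenced == 1352
    assert summary.n_failed == 74
    assert summary.n_solved == 508
    assert summary.diagnostic_yield == pytest.approx(508 / 1278)
    d = summary.as_dict()
    assert d["inheritance_breakdown"]["AR"] == {"solved": 379, "share_pct": 74.6}
    assert d["inheritance_breakdown"]["AD"] == {"solved": 105, "share_pct": 20.7}
    assert d["inheritance_breakdown"]["XL"] == {"solved": 18, "share_pct": 3.5}
    assert d["inheritance_breakdown"]["MT"] == {"solved": 6, "share_pct": 1.2}
    shares = [v["share_pct"] for v in d["inheritance_breakdown"].values()]
    assert sum(shares) == pytest.approx(100.0, abs=0.2)


def test_all_unsolved_cohort_has_zero_yield(gene_table):
    verdicts = [_synthetic_verdict(i, VerdictStatus.UNSOLVED) for i in range(10)]
    assert cohort_summary(verdicts, genes=gene_table).diagnostic_yield == 0.0


def test_gene_ranking_matches_sort_oracle(gene_table):
    rng = random.Random(3)
    genes5 = ["ABCA4", "PRPH2", "CDHR1", "RP1L1", "ROM1"]
    verdicts = [
        _synthetic_verdict(i, VerdictStatus.VERY_LIKELY_SOLVED, rng.choice(genes5))
        for i in range(97)
    ]
    summary = cohort_summary(verdicts, genes=gene_table)
    counts = {}
    for v in verdicts:
        counts[v.causal_gene] = counts.get(v.causal_gene, 0) + 1
    expected = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    assert [(g, n) for g, n, _ in summary.gene_ranking] == expected
    assert sum(s for _, _, s in summary.gene_ranking) == pytest.approx(1.0)


def test_round_half_up_matches_reported_convention():
    assert round_half_up_pct(379 / 508) == 74.6
    assert round_half_up_pct(31 / 2704, 2) == 1.15
    assert round_half_up_pct(0.39749) == 39.7
    assert round_half_up_pct(0.1235) == 12.4  # half rounds up, not to even


# ---------------------------------------------------------------------------
# Carrier census
# ---------------------------------------------------------------------------


def _random_cohort_for_census(rng, gene_table):
    from macpen.model import Verdict

    genotypes, verdicts = {}, []
    for i in range(120):
        pid = f"C{i:04d}"
        calls = []
        for j in range(rng.randint(0, 4)):
            gene = rng.choice(list(gene_table))
            cdna = rng.choice(["c.2588G>C", f"c.{j+1}A>G"]) if gene == "ABCA4" else f"c.{j+1}A>G"
            sev = (
                rng.choice([None, Severity.MILD, Severity.SEVERE])
                if gene == "ABCA4"
                else None
            )
            v = make_variant(
                gene=gene, cdna=cdna, pos=10 * j + 10,
                gnomad_af=rng.random() * 0.004,
                acmg_class=rng.choice([None, 2, 3, 4, 5]),
                abca4_severity=sev,
            )
            calls.append((v, rng.choice([Zygosity.HET, Zygosity.HOM])))
        genotypes[pid] = make_proband(pid=pid, variants=calls)
        solved = rng.random() < 0.4
        verdicts.append(
            Verdict(
                proband_id=pid,
                status=VerdictStatus.VERY_LIKELY_SOLVED if solved else VerdictStatus.UNSOLVED,
                causal_gene=rng.choice(list(gene_table)) if solved else None,
                rationale=["r"],
            )
        )
    return verdicts, genotypes


def test_carrier_census_matches_bruteforce_recount(gene_table):
    rng = random.Random(29)
    verdicts, genotypes = _random_cohort_for_census(rng, gene_table)
    census = carrier_census(verdicts, genotypes, gene_table)

    # independent re-count
    expected = {"solved": 0, "unsolved": 0}
    for v in verdicts:
        geno = genotypes[v.proband_id]
        hit = False
        for var, zyg in geno.variants:
            if zyg is not Zygosity.HET or var.gene == v.causal_gene:
                continue
            if var.gene == "ABCA4" and var.cdna == "c.2588G>C":
                continue
            if var.gene == "ABCA4" and var.abca4_severity not in (None, Severity.NO_EFFECT):
                hit = True
            elif (
                gene_table[var.gene].inheritance is Inheritance.AR
                and var.acmg_class in (4, 5)
            ):
                hit = True
        expected["solved" if v.solved else "unsolved"] += int(hit)
    assert census == expected


def test_excluded_variant_alone_does_not_make_a_carrier(gene_table):
    from macpen.model import Verdict

    v = make_variant(gene="ABCA4", cdna="c.2588G>C", abca4_severity=Severity.MILD,
                     gnomad_af=0.004, acmg_class=5)
    genotypes = {"P1": make_proband(pid="P1", variants=[(v, Zygosity.HET)])}
    verdicts = [Verdict(proband_id="P1", status=VerdictStatus.UNSOLVED, rationale=["r"])]
    assert carrier_census(verdicts, genotypes, gene_table) == {"solved": 0, "unsolved": 0}


def test_solved_proband_with_extra_het_pathogenic_ar_variant_is_counted(gene_table):
    from macpen.model import Verdict

    causal = make_variant(gene="RP1L1", cdna="c.1509del", consequence="frameshift",
                          gnomad_af=None, acmg_class=5, pos=10)
    extra = make_variant(gene="CDHR1", cdna="c.783G>A", gnomad_af=0.003, acmg_class=5, pos=20)
    genotypes = {
        "P1": make_proband(pid="P1", variants=[(causal, Zygosity.HOM), (extra, Zygosity.HET)])
    }
    verdicts = [
        Verdict(proband_id="P1", status=VerdictStatus.VERY_LIKELY_SOLVED,
                causal_gene="RP1L1", rationale=["r"])
    ]
    assert carrier_census(verdicts, genotypes, gene_table) == {"solved": 1, "unsolved": 0}
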