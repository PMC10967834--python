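import pandas as pd
import pytest

from macpen.model import (
    GeneInfo,
    Inheritance,
    ProbandGenotype,
    SpliceScores,
    VariantRecord,
    Zygosity,
)

GENE_MODES = {
    "ABCA4": "AR",
    "CDHR1": "AR",
    "CNGB3": "AR",
    "RP1L1": "AR",
    "ROM1": "AR",
    "NMNAT1": "AR",
    "PRPH2": "AD",
    "BEST1": "AD",
    "CACNA1F": "XL",
    "RPGR": "XL",
    "MT-TL1": "MT",
}


@pytest.fixture
def gene_table():
    return {
        g: GeneInfo(gene=g, inheritance=Inheritance(m)) for g, m in GENE_MODES.items()
    }


@pytest.fixture
def gene_table_file(tmp_path):
    path = tmp_path / "genes.tsv"
    pd.DataFrame(
        {"gene": list(GENE_MODES), "inheritance": list(GENE_MODES.values())}
    ).to_csv(path, sep="\t", index=False)
    return path


def make_variant(
    gene="CDHR1",
    cdna="c.1A>G",
    consequence="missense",
    gnomad_af=0.0001,
    acmg_class=5,
    pos=100,
    splice_scores=None,
    **kw,
):
    return VariantRecord(
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="G",
        gene=gene,
        cdna=cdna,
        consequence=consequence,
        gnomad_af=gnomad_af,
        acmg_class=acmg_class,
        splice_scores=splice_scores,
        **kw,
    )


def make_proband(pid="P1", phenotype="MD", variants=(), **kw):
    return ProbandGenotype(
        proband_id=pid, phenotype=phenotype, variants=list(variants), **kw
    )
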