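import pytest

from oncopanel.simulate import (
    ArtifactSim,
    CnvSim,
    DeSim,
    GermlineSim,
    HotspotSim,
    PrivateSomaticSim,
    SimConfig,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=248956422>
##contig=<ID=chr2,length=242193529>
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=A,Type=String,Description="Effect class">
##INFO=<ID=PCHANGE,Number=A,Type=String,Description="Protein change">
##INFO=<ID=DSCORE,Number=A,Type=Float,Description="Deleteriousness score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path, body, samples=("S1", "S2")):
    cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *samples])
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


@pytest.fixture
def small_sim_config():
    """Reduced panel for fast round-trip and construction tests."""
    return SimConfig(
        seed=42,
        germline=GermlineSim(count=20),
        artifact=ArtifactSim(count=5),
        somatic_private=PrivateSomaticSim(per_line=1),
        somatic_hotspot=HotspotSim(count=4),
        cnv=CnvSim(n_genes=200),
        de=DeSim(n_genes=300, n_group2=4, n_up=10, n_down=15),
    )
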