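import pytest

from tfcobind.genomic_io import GeneModel, GenomicInterval, Peak
from tfcobind.simulate import SyntheticConfig, simulate_dataset


def make_peak(chrom="chr1", start=100, end=600, summit=None, factor="A", condition="", name="p", score=1.0):
    if summit is None:
        summit = (start + end) // 2
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        summit=summit,
        factor=factor,
        condition=condition,
        score=score,
        name=name,
    )


def make_gene(
    gene_id="gA",
    chrom="chr1",
    start=10_000,
    end=20_000,
    strand="+",
    exons=None,
    cds=None,
    utr3=None,
):
    if exons is None:
        exons = ((start, start + 1000), (end - 1000, end))
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        exons=tuple(exons),
        cds=cds,
        utr3=utr3,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (seed 7), shared across tests."""
    return simulate_dataset(SyntheticConfig(seed=7))


@pytest.fixture
def peak_factory():
    return make_peak


@pytest.fixture
def gene_factory():
    return make_gene
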