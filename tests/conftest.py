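import pytest

from itgscan import GeneRecord, GenomicInterval, SimConfig, write_fixture


@pytest.fixture
def toy_genes():
    """Five reference genes on two chromosomes for distance tests."""
    return [
        GeneRecord("gA", GenomicInterval("chr1", 1000, 3000, "+")),
        GeneRecord("gB", GenomicInterval("chr1", 10000, 12000, "-")),
        GeneRecord("gC", GenomicInterval("chr1", 30000, 31000, "+")),
        GeneRecord("gD", GenomicInterval("chr2", 500, 2500, "+")),
        GeneRecord("gE", GenomicInterval("chr2", 40000, 45000, "-")),
    ]


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small simulated fixture bundle shared across pipeline/IO tests."""
    out = tmp_path_factory.mktemp("fixtures") / "sim"
    write_fixture(SimConfig(seed=7), out)
    return out
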