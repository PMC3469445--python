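import numpy as np
import pytest

from zmpipe.genome import GeneModel, GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def plus_gene():
    return GeneModel(id="g+", chrom="chr1", start=2000, end=9000, strand="+")


@pytest.fixture
def minus_gene():
    return GeneModel(id="g-", chrom="chr1", start=2000, end=9000, strand="-")


@pytest.fixture
def random_genome(rng):
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    return GenomeSequence({"chr1": seq})
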