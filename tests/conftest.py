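import pytest

from dnsvkit.genome import synthetic_genome
from dnsvkit.model import AnalysisParams


@pytest.fixture
def params():
    return AnalysisParams()


@pytest.fixture
def toy_genome():
    return synthetic_genome(n_chroms=3, chrom_length=100_000_000)
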