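import numpy as np
import pytest

from smadpipe.annotation import GeneModel
from smadpipe.synthetic import SyntheticGenome


@pytest.fixture
def small_genome():
    """Two short chromosomes with a handful of genes."""
    genes = (
        GeneModel("GA", "chr1", "+", 20_000, 30_000),
        GeneModel("GB", "chr1", "-", 80_000, 70_000),
        GeneModel("GC", "chr2", "+", 50_000, 60_000),
    )
    return SyntheticGenome(
        chrom_sizes={"chr1": 200_000, "chr2": 150_000}, genes=genes
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
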