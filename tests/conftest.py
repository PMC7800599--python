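import numpy as np
import pytest

from promoterscope.genome_model import ChromSizes, GeneModel, build_partition
from promoterscope.synthetic_data import SimulationConfig


@pytest.fixture
def chrom_sizes():
    return ChromSizes({"chr2L": 50_000, "chr2R": 30_000})


@pytest.fixture
def one_gene_partition():
    """The worked single-gene example: + gene [1000, 2000) on 3000 bp."""
    sizes = ChromSizes({"chrA": 3000})
    genes = [GeneModel("g1", "chrA", 1000, 2000, "+")]
    return build_partition(genes, sizes, (100, 100), (100, 100)), sizes, genes


@pytest.fixture
def small_config():
    return SimulationConfig.small(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
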