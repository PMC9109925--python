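import numpy as np
import pytest

from sgnb.read_typing import DesignInfo
from sgnb.simulate import SimConfig, generate_gene_models


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally rich transcriptome configuration."""
    return SimConfig(n_genes=20, samples_per_condition=3, reads_per_gene=500, seed=0)


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    models, isoforms = generate_gene_models(small_config, np.random.default_rng(0))
    return models, isoforms


@pytest.fixture
def design_3v3():
    return DesignInfo({f"c0_s{i}": 0 for i in range(1, 4)} | {f"c1_s{i}": 1 for i in range(1, 4)})
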