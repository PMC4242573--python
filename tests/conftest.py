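import numpy as np
import pytest

from cubne import seqio, simulate


@pytest.fixture(scope="session")
def code():
    return seqio.STANDARD_CODE


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial simulated genome configuration."""
    return simulate.SimulationConfig(
        seed=7, n_genes=12, codons_per_gene=150, intron_length=1200,
    )


@pytest.fixture(scope="session")
def small_records(small_config):
    return simulate.gen_genes(small_config)


@pytest.fixture(scope="session")
def small_genome(small_records):
    genome, bed = simulate.assemble_genome(small_records)
    return genome, bed
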