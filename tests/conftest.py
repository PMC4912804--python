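import numpy as np
import pytest

from pfinish import GenomeSpec, generate_plastome, simulate_reads
from pfinish.sequtils import random_seq


@pytest.fixture(scope="session")
def small_spec():
    return GenomeSpec(
        lsc_len=3000, ir_len=800, ssc_len=600, spacer_offset=400, seed=42
    )


@pytest.fixture(scope="session")
def small_plastome(small_spec):
    """A 5.2 kb quadripartite plastome with ground truth."""
    return generate_plastome(small_spec)


@pytest.fixture(scope="session")
def small_reads(small_plastome):
    plastome, _truth = small_plastome
    return simulate_reads(
        [(plastome.sequence, 1.0)], read_len=100, mean_depth=40, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_dna(rng):
    def make(length, gc=0.4):
        return random_seq(length, gc, rng)

    return make
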