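import numpy as np
import pytest

from ophanno.synthetic_data import GenomeConfig, simulate_genome


@pytest.fixture(scope="session")
def sim():
    """Study-scale simulated genome (100 kb, 100 ORFs, 6 hrs) with truth."""
    return simulate_genome(GenomeConfig(), seed=11)


@pytest.fixture(scope="session")
def small_sim():
    """Small genome for fast integration tests."""
    cfg = GenomeConfig(length=24_000, n_orfs=18, n_hrs=3)
    return simulate_genome(cfg, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_genome_seq(rng, length, gc=0.5):
    p = [gc / 2, (1 - gc) / 2, (1 - gc) / 2, gc / 2]
    return "".join(rng.choice(list("CATG"), size=length, p=p))
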