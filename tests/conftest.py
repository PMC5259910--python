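import numpy as np
import pytest

from rsapred import load_bundled_table
from rsapred.synthetic import SynthConfig, gen_chain


@pytest.fixture(scope="session")
def table():
    return load_bundled_table()


@pytest.fixture(scope="session")
def small_table(table):
    """First 8 complete indices of the bundled snapshot."""
    return table.subset(table.accessions[:8])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def chain_and_profile(rng):
    cfg = SynthConfig(rng_seed=0)
    return gen_chain(cfg, rng, chain_id="fix1")
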