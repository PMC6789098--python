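import numpy as np
import pytest

import scpipesim as sps


@pytest.fixture(scope="session")
def umi_fixture():
    """Small UMI-like parameter bundle shared across tests."""
    return sps.make_fixture("umi_like", n_genes=2000, seed=1)


@pytest.fixture(scope="session")
def readlevel_fixture():
    return sps.make_fixture("readlevel_like", n_genes=1500, seed=2)


@pytest.fixture(scope="session")
def null_dataset(umi_fixture):
    """p_de = 0 dataset: the two groups are exchangeable."""
    setup = sps.DESetup(n1=96, n2=96, n_genes=2000, p_de=0.0, seed=7)
    return sps.simulate_counts(umi_fixture.params, setup,
                               np.random.default_rng(7),
                               spike_params=umi_fixture.spikes)


@pytest.fixture(scope="session")
def de_dataset(umi_fixture):
    """5% symmetric DE at 96 vs 96 cells, with spike-ins."""
    setup = sps.DESetup(n1=96, n2=96, n_genes=2000, p_de=0.05,
                        pattern="symmetric", seed=11)
    return sps.simulate_counts(umi_fixture.params, setup,
                               np.random.default_rng(11),
                               spike_params=umi_fixture.spikes)
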