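import dataclasses

import numpy as np
import pytest

from epimem.params import (
    BcpnnParams,
    ExperimentConfig,
    LayoutParams,
    NeuronParams,
    ReceptorParams,
    StpParams,
)


@pytest.fixture(scope="session")
def neuron_params():
    return NeuronParams()


@pytest.fixture(scope="session")
def receptor_params():
    return ReceptorParams()


@pytest.fixture(scope="session")
def stp_params():
    return StpParams()


@pytest.fixture(scope="session")
def bcpnn_params():
    return BcpnnParams()


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature two-network model for engine-level tests: 2 HCs of
    4 MCs with 10 pyramidal + 2 basket cells per MC per network."""
    cfg = ExperimentConfig()
    cfg.layout = LayoutParams(n_hc=2, n_mc_per_hc=4, n_pyr_per_mc=10,
                              n_basket_per_mc=2)
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
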