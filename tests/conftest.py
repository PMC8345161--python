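import numpy as np
import pytest

from spatialqsp.lineage import derive_lineage_rates
from spatialqsp.registry import default_registry
from spatialqsp.synapse import SynapseParams


@pytest.fixture
def reg():
    return default_registry()


@pytest.fixture
def synapse_params(reg):
    return SynapseParams.from_registry(reg)


@pytest.fixture
def rates():
    # fast-relaxing lineage used across ABM tests
    return derive_lineage_rates(r=0.03, k=0.5, r_p=0.3, mu=0.05, d_max=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
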