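import numpy as np
import pytest

from mbco import GenerationConfig, sequential_two_mediator, simulate_dataset


@pytest.fixture(scope="session")
def chain_model():
    """The hypothesized mediation chain M1~X, M2~M1, Y~M2."""
    return sequential_two_mediator()


@pytest.fixture(scope="session")
def general_model():
    """The two-mediator model with free direct paths b4-b6."""
    return sequential_two_mediator(direct_paths=True)


@pytest.fixture(scope="session")
def data_h1(chain_model):
    """N=200 dataset with a clear indirect effect (b1=b2=b3=0.36)."""
    return simulate_dataset(chain_model, GenerationConfig(beta=0.36, n=200, seed=42))


@pytest.fixture(scope="session")
def data_h0(chain_model):
    """N=200 dataset generated under the null (all chain paths zero)."""
    return simulate_dataset(chain_model, GenerationConfig(beta=0.0, n=200, seed=43))


@pytest.fixture(scope="session")
def data50(general_model):
    """Small fixed N=50 dataset for oracle comparisons (general model)."""
    return simulate_dataset(
        general_model,
        GenerationConfig(beta=0.36, n=50, seed=7, overrides={"b4": 0.1, "b5": 0.1, "b6": 0.1}),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
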