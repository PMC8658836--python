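import numpy as np
import pytest

from parsiopt.search_space import (
    ArchitectureConfig,
    Factor,
    HyperparameterSpace,
    default_space,
)


@pytest.fixture(scope="session")
def space():
    return default_space()


@pytest.fixture()
def toy_space():
    """2-factor space with 2 and 3 levels: 6 grid points."""
    return HyperparameterSpace(
        (
            Factor("alpha", "quantitative", (1, 2)),
            Factor("beta", "qualitative", ("x", "y", "z")),
        )
    )


@pytest.fixture()
def bijective_space():
    """Nine 4-level factors: chromosome <-> config is a bijection on all
    18 bits (no modulo wrap), as needed for bit-counting surrogates."""
    return HyperparameterSpace(
        tuple(Factor(f"f{i}", "quantitative", (0, 1, 2, 3)) for i in range(9))
    )


@pytest.fixture(scope="session")
def good_arch():
    """A sensible architecture for the learnable synthetic datasets."""
    return ArchitectureConfig.from_mapping(
        {
            "neurons_layer1": 100,
            "neurons_layer2": 0,
            "neurons_layer3": 0,
            "dropout": 0.0,
            "learning_rate": 1e-2,
            "epochs": 50,
            "activation": "relu",
            "optimizer": "adam",
            "penalty": "L1",
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
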