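import numpy as np
import pandas as pd
import pytest

from hematlas import ExpressionMatrix, SyntheticConfig, generate_atlas


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def atlas(default_config):
    """Default synthetic atlas + ground truth, fixed seed, shared read-only."""
    return generate_atlas(default_config, seed=1)


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
        index=["p1", "p2", "p3"],
    )
    return ExpressionMatrix(data, scale="transformed")


def make_matrix(values, probes=None, samples=None, scale="transformed") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), scale=scale)
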