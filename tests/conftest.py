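import numpy as np
import pytest

from qmorph import SyntheticSpec, generate, generate_dataset


@pytest.fixture(scope="session")
def small_table():
    """Clean 200-row, 14-class table with 5 planted informative features."""
    return generate_dataset(SyntheticSpec(n_neurons=200, seed=1))


@pytest.fixture(scope="session")
def artifact_table():
    """300-row table with planted missing cells, zero somas and outliers."""
    spec = SyntheticSpec(
        n_neurons=300, seed=3, missing_rate=0.02, zero_soma_rate=0.03,
        outlier_rate=0.05,
    )
    return generate(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
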