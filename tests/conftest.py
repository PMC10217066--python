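import numpy as np
import pytest

from somdbn import FeatureTable, generate_pima_like_cohort


@pytest.fixture(scope="session")
def pima_cohort():
    """Synthetic screening cohort with the published counts planted."""
    table, truth = generate_pima_like_cohort(seed=0)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_table():
    values = np.array(
        [
            [1.0, 10.0, 0.5],
            [2.0, 0.0, 1.5],
            [3.0, 30.0, 2.5],
        ]
    )
    return FeatureTable(values, ("a", "b", "c"), None, np.array([0, 1, 0]))
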