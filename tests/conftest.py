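import numpy as np
import pytest

from dbloss.balance import BalanceParams, ClassCounts, build_weight_table


@pytest.fixture
def lesion_counts() -> ClassCounts:
    """Training tallies of the three-class colonoscopy lesion profile."""
    return ClassCounts(("adenoma", "cancer", "polyp"), (838, 224, 305))


@pytest.fixture
def lesion_table(lesion_counts):
    """Weight table at the default hyperparameters (beta 0.99, rho 0.25)."""
    return build_weight_table(lesion_counts, BalanceParams(beta=0.99, rho=0.25))


@pytest.fixture
def uniform_table():
    return build_weight_table(
        ClassCounts(("a", "b", "c"), (100, 100, 100)), BalanceParams(0.9, 0.5)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
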