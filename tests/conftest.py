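import numpy as np
import pytest

from mocu_design.evaluation import generate_random_network, sample_uncertain_positions
from mocu_design.network import BooleanNetwork
from mocu_design.uncertainty import UncertaintyClass


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)


def random_model(rng, n=3, p=0.01):
    """A random majority-vote BNp small enough for brute-force checks."""
    R = generate_random_network(n, predictors_per_gene=min(3, n - 1), rng=rng)
    return BooleanNetwork.from_regulatory_matrix(R, p=p)


def random_class(rng, n=3, k=2, p=0.01):
    """A random uncertainty class on a small network."""
    R = generate_random_network(n, predictors_per_gene=min(3, n - 1), rng=rng)
    positions = sample_uncertain_positions(R, k, rng)
    return UncertaintyClass(R, positions, p=p)
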