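import numpy as np
import pytest

from famnet.synthetic_data import (
    GGMTruth, default_triad_communities, family_triad_truth,
    simulate_cross_sectional,
)

EBIC = {"penalty_selection": "ebic"}


@pytest.fixture(scope="session")
def triad_truth():
    return family_triad_truth()


@pytest.fixture(scope="session")
def triad_data(triad_truth):
    return simulate_cross_sectional(triad_truth, 5000, seed=101)


@pytest.fixture(scope="session")
def small_bridge_truth():
    """4-node truth with one child-mother bridge edge (pcor 0.25)."""
    names = ["c_a", "c_b", "m_a", "m_b"]
    K = np.eye(4)

    def setp(i, j, r):
        K[i, j] = K[j, i] = -r

    setp(0, 1, 0.3)
    setp(2, 3, 0.3)
    setp(0, 2, 0.25)
    return GGMTruth(names, K, default_triad_communities(names))
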