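import numpy as np
import pytest
import scipy.sparse as sp

import coaware as ca


@pytest.fixture(scope="session")
def small_net():
    """A 40-node, 2-layer weighted multiplex with a positively correlated issue."""
    net = ca.generate_scale_free_multiplex(40, 2, 2, seed=42)
    awbar = ca.overlapping_awareness(net.aw, ca.IssueCorrelations((0.8,)))
    return ca.compute_weights(net, awbar)


@pytest.fixture(scope="session")
def elected(small_net):
    """(ranking, rate matrices, beta_bar, lam_bar, contacts) on the small fixture."""
    params = ca.RateParameters()
    ranking = ca.coupled_centrality(small_net)
    rm = ca.build_rate_matrices(small_net, params)
    beta_bar, lam_bar = ca.elected_rates(rm, ranking.elected_layer)
    contacts = ca.contact_matrix(small_net, ranking.elected_layer)
    return ranking, rm, beta_bar, lam_bar, contacts


@pytest.fixture
def path3():
    """Binary path graph 0-1-2 as a sparse contact matrix."""
    return sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float))
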