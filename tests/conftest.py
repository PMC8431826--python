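import numpy as np
import networkx as nx
import pandas as pd
import pytest

from nctpipe import BehaviorGenConfig, generate_trials


@pytest.fixture
def two_cliques():
    """Two disconnected 4-cliques; planted labels [0]*4 + [1]*4."""
    a = np.zeros((8, 8))
    k4 = nx.to_numpy_array(nx.complete_graph(4))
    a[:4, :4] = k4
    a[4:, 4:] = k4
    return a, np.array([0] * 4 + [1] * 4)


@pytest.fixture
def barbell():
    """Two 3-cliques joined by a single bridge edge (nodes 2 and 3)."""
    a = nx.to_numpy_array(nx.barbell_graph(3, 0))
    return a, np.array([0] * 3 + [1] * 3)


@pytest.fixture
def joined_five_cliques():
    """Two 5-cliques joined by one unit edge; planted labels alongside."""
    a = nx.to_numpy_array(nx.barbell_graph(5, 0))
    return a, np.array([0] * 5 + [1] * 5)


def make_trials(n_active=6, n_sham=5, n_trials=20, seed=0, boundary_sd=20.0,
                **beta_overrides):
    """Trial table with independent streams for covariates and noise."""
    cfg = BehaviorGenConfig(n_active=n_active, n_sham=n_sham, n_trials=n_trials,
                            seed=seed, **beta_overrides)
    boundary = np.random.default_rng(seed + 10_000).normal(0.0, boundary_sd,
                                                           cfg.n_subjects)
    return generate_trials(cfg, boundary), cfg


@pytest.fixture
def small_trials():
    return make_trials()[0]
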