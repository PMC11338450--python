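import dataclasses

import numpy as np
import pytest

from scrnmf import (
    CountMatrix,
    Hyperparams,
    build_graphs,
    calibrate_dropout,
    preprocess,
)
from scrnmf.simulate import SimParams, simulate_groups


@pytest.fixture
def tiny_counts():
    return CountMatrix(
        np.array([[5.0, 0.0], [1.0, 0.0], [2.0, 0.0]]).T.T,  # 3 genes x 2 cells
        ["g1", "g2", "g3"],
        ["c1", "c2"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small 4-group simulation with ~70 % zeros, shared across tests."""
    params = SimParams(n_genes=120, n_cells=80, n_groups=4, seed=7)
    calibrated, _ = calibrate_dropout(params, 0.70, tol=0.02)
    return simulate_groups(calibrated)


@pytest.fixture(scope="session")
def small_processed(small_sim):
    return preprocess(small_sim.observed_count_matrix(), min_cells=2, n_top=120)


@pytest.fixture(scope="session")
def small_graphs(small_processed):
    return build_graphs(small_processed)


@pytest.fixture
def default_hyper():
    return Hyperparams(k=5, sigma=1.0, alpha=0.1, beta=0.1, lam=0.1)
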