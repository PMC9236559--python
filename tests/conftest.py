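import numpy as np
import pytest

from notreached.model_core import Dataset, QMatrix
from notreached.simulate import SimulationCondition, simulate_condition


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_q():
    return QMatrix(np.array([[1, 0], [0, 1], [1, 1]]))


@pytest.fixture
def toy_dataset(tiny_q):
    """3-item, 2-attribute dataset with one dropout, small enough for
    enumeration oracles."""
    Y = np.array([[1.0, 0.0, 1.0],
                  [1.0, np.nan, np.nan],
                  [0.0, 1.0, 0.0]])
    D = np.array([[0, 0, 0],
                  [0, 1, 1],
                  [0, 0, 0]])
    return Dataset(Y=Y, D=D, Q=tiny_q)


@pytest.fixture(scope="session")
def study1_fit():
    """One reduced NMAR fit on a Study-I style dataset, shared by tests that
    only inspect the fitted object."""
    from notreached.estimator import DinaDropoutModel

    cond = SimulationCondition(N=200, J=20, K=3, rho=-0.3,
                               dropout_level="medium", seed=99)
    dataset, truth = simulate_condition(cond, 0)
    est = DinaDropoutModel(model="nmar", chain_length=1200, burn_in=600,
                           n_chains=1, random_state=7,
                           compute_fit_metrics=True).fit(dataset)
    return est, dataset, truth
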