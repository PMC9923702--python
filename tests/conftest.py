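import logging
import warnings

import numpy as np
import pytest

import bltsa
from bltsa.preprocess import Embedding, ExpressionMatrix

logging.getLogger("bltsa").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trifurcation_noiseless():
    return bltsa.simulate_geometric_trifurcation(seed=0, noise_high=0.0)


@pytest.fixture(scope="session")
def trifurcation_noisy():
    return bltsa.simulate_geometric_trifurcation(seed=0)


def as_expression(traj):
    """Wrap a simulated trajectory as an ExpressionMatrix with time labels."""
    return ExpressionMatrix(
        traj.matrix, list(traj.feature_ids), list(traj.cell_ids), traj.true_tau
    )


@pytest.fixture(scope="session")
def line_embedding():
    """30 evenly spaced points on a straight 2-D segment."""
    t = np.linspace(0.0, 1.0, 30)
    coords = np.vstack([t, 0.5 * t])
    return Embedding(coords, [f"c{i}" for i in range(30)])
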