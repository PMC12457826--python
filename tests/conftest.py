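import numpy as np
import pytest
from scipy.special import ndtri

from ordcause import LatentGaussianDAG, chain_model
from ordcause.synthetic import equal_level_thresholds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def probe_sample():
    """Deterministic standard-normal-like sample (normal scores, n=100)."""
    return ndtri((np.arange(1, 101) - 0.5) / 100)


@pytest.fixture
def chain3():
    """Standardized chain X1 -> X2 -> X3 with b = 0.8 and 3 equal levels."""
    return chain_model(m=3, b=0.8, levels=3)


@pytest.fixture
def collider3():
    """A -> C <- B with coefficient 0.7 and 3 equal levels per node."""
    adj = np.zeros((3, 3), dtype=bool)
    adj[0, 2] = adj[1, 2] = True
    coef = np.where(adj, 0.7, 0.0)
    model = LatentGaussianDAG(
        nodes=["A", "B", "C"],
        adjacency=adj,
        coefficients=coef,
        means=np.zeros(3),
        cond_variances=np.ones(3),
        thresholds=[equal_level_thresholds(3) for _ in range(3)],
    )
    return model.standardized()
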