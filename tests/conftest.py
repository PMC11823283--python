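import numpy as np
import pytest

import dsfm


@pytest.fixture
def pattern():
    return dsfm.default_pattern()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_conforming_loadings(pattern, rng, scale=1.0):
    """Random loadings respecting the mask with positive anchors."""
    vals = np.where(pattern.mask,
                    scale * rng.standard_normal(pattern.mask.shape), 0.0)
    for (k, j) in pattern.anchors:
        vals[k, j] = abs(vals[k, j]) + 0.1
    return dsfm.LoadingsMatrix(values=vals, pattern=pattern)


@pytest.fixture
def path3_graph():
    """3-node path graph 0-1-2."""
    return dsfm.AdjacencyGraph(n_units=3, edges=np.array([[0, 1], [1, 2]]))


@pytest.fixture
def tiny_panel():
    """2 units x 2 times x 1 outcome, no censoring."""
    counts = np.array([[[3], [1]], [[0], [2]]])
    pops = np.array([[1.0e4, 1.1e4], [2.0e4, 2.1e4]])
    return dsfm.CountPanel(counts=counts, censored=np.zeros_like(counts, bool),
                           populations=pops)
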