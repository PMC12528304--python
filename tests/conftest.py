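import numpy as np
import pytest

from genspin import InteractionGraph, ModelParams


@pytest.fixture
def path3():
    """Path graph 0-1-2."""
    return InteractionGraph(n=3, edges=np.array([[0, 1], [1, 2]]))


@pytest.fixture
def dimer():
    return InteractionGraph(n=2, edges=np.array([[0, 1]]))


@pytest.fixture
def single_node():
    return InteractionGraph(n=1, edges=np.empty((0, 2)))


@pytest.fixture
def double_well_params():
    """Supercritical three-fixed-point regime (7-state model, d=2)."""
    return ModelParams(beta=3.0, sigma=1.0, tau=0.3, k=3)
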