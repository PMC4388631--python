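import numpy as np
import pytest

from fluxhr import StoichiometricModel, make_hypercube


@pytest.fixture
def toy_chain_model():
    """Linear chain A -> B -> C: S = [[1,-1,0],[0,1,-1]], all fluxes in [0,1].

    Steady state forces v1 = v2 = v3, so the polytope is a 1-D segment.
    """
    return StoichiometricModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["R1", "R2", "R3"],
        S=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        lower_bounds=np.zeros(3),
        upper_bounds=np.ones(3),
    )


@pytest.fixture
def unit_square():
    return make_hypercube(2)


@pytest.fixture
def triangle():
    """{v >= 0, v1 + v2 <= 1} as a full-dimensional polytope."""
    from fluxhr import Polytope

    G = np.array([[-1.0, 0.0], [0.0, -1.0], [1.0, 1.0]])
    h = np.array([0.0, 0.0, 1.0])
    return Polytope(anchor=np.zeros(2), basis=np.eye(2), G=G, h=h)
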