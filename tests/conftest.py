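import numpy as np
import pytest

from grnscape.network import RegulatoryNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_gene_chain():
    """Input gene 0 activating gene 1 (J_10 = +1)."""
    return RegulatoryNetwork(
        2, np.array([[0, 0], [1, 0]], dtype=np.int8), output_node=1
    )


@pytest.fixture
def three_gene_chain():
    """0 -> 1 -> 2, all activating."""
    J = np.zeros((3, 3), dtype=np.int8)
    J[1, 0] = 1
    J[2, 1] = 1
    return RegulatoryNetwork(3, J, output_node=2)
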