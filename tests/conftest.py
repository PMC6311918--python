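import numpy as np
import pytest

import birwnet as bw


@pytest.fixture
def diag2_assoc() -> bw.AssociationMatrix:
    """Two diseases, two lncRNAs, one association each (identity adjacency)."""
    return bw.AssociationMatrix(np.eye(2), ("D1", "D2"), ("L1", "L2"))


@pytest.fixture(scope="session")
def planted():
    """The default planted-block network shared across slower tests."""
    cfg = bw.SyntheticConfig(seed=0)
    assoc, expr, labels = bw.generate_network(cfg)
    return cfg, assoc, expr, labels


def random_assoc(rng: np.random.Generator, nd: int, nl: int, p: float = 0.5):
    """Random binary association matrix with at least one edge."""
    values = (rng.random((nd, nl)) < p).astype(float)
    if values.sum() == 0:
        values[rng.integers(nd), rng.integers(nl)] = 1.0
    return bw.AssociationMatrix(
        values,
        tuple(f"D{i}" for i in range(nd)),
        tuple(f"L{j}" for j in range(nl)),
    )
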