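import numpy as np
import pytest

from canetx.dataio import OmicsMatrix
from canetx.netinfer import AssociationNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, group=None, **kw):
    """Small OmicsMatrix helper with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if group is None:
        group = ("cancer",) * n
    return OmicsMatrix(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(n)),
        feature_ids=tuple(f"f{j}" for j in range(p)),
        group=tuple(group),
        **kw,
    )


def net_from_weights(w):
    w = np.asarray(w, dtype=float)
    return AssociationNetwork(
        weights=w, node_ids=tuple(f"n{i}" for i in range(w.shape[0]))
    )


@pytest.fixture
def small_net():
    # path n0 - n1 - n2 plus isolated n3
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 0.5
    w[1, 2] = w[2, 1] = -0.3
    return net_from_weights(w)
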