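import numpy as np
import pytest

from dynseg.containers import NetworkAtlas


@pytest.fixture
def atlas4x3() -> NetworkAtlas:
    """12 nodes in 4 equal networks."""
    nodes = tuple(f"n{i}" for i in range(12))
    nets = ["A", "B", "C", "D"]
    return NetworkAtlas(nodes, {n: nets[i // 3] for i, n in enumerate(nodes)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def block_matrix(labels: np.ndarray, within: float, between: float) -> np.ndarray:
    """Block connectivity matrix with zero diagonal (shared test helper)."""
    same = labels[:, None] == labels[None, :]
    W = np.where(same, within, between).astype(float)
    np.fill_diagonal(W, 0.0)
    return W
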