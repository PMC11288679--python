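import numpy as np
import pandas as pd
import pytest

from antnet.network import WeightedNetwork, build_network


@pytest.fixture
def triangle() -> WeightedNetwork:
    W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return build_network(W, ids=["a", "b", "c"])


@pytest.fixture
def two_triangles() -> WeightedNetwork:
    """Two disjoint unit-weight triangles (hard split has Q = 0.5)."""
    W = np.zeros((6, 6))
    for blk in ((0, 1, 2), (3, 4, 5)):
        for i in blk:
            for j in blk:
                if i != j:
                    W[i, j] = 1.0
    return build_network(W)


def random_weighted_network(rng: np.random.Generator, n: int | None = None,
                            p: float = 0.5) -> WeightedNetwork:
    """Random integer-weighted graph for conservation/oracle tests."""
    if n is None:
        n = int(rng.integers(5, 13))
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < p
    W[iu[present], ju[present]] = rng.integers(1, 20, size=present.sum())
    W = W + W.T
    return build_network(W)


@pytest.fixture
def detections_two_ants() -> pd.DataFrame:
    """Two ants, 4 frames, overlapping in frames 0-2 only."""
    rows = []
    for f in range(4):
        near = f < 3
        rows.append((float(f), "a", 0.0, 0.0, 0.0, "nest"))
        rows.append((float(f), "b", 0.6 if near else 10.0, 0.0, np.pi, "nest"))
    return pd.DataFrame(
        rows, columns=["time_s", "ant_id", "x", "y", "angle_rad", "arena"]
    )
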