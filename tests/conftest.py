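from __future__ import annotations

import numpy as np
import pytest

from temporalcorr import NodeRegistry, Snapshot, TemporalNetwork


def random_network(
    rng: np.random.Generator,
    n_nodes: int | None = None,
    n_snapshots: int | None = None,
    p_edge: float = 0.2,
) -> TemporalNetwork:
    """Random directed temporal network with iid Bernoulli edges."""
    if n_nodes is None:
        n_nodes = int(rng.integers(2, 21))
    if n_snapshots is None:
        n_snapshots = int(rng.integers(2, 11))
    registry = NodeRegistry(f"n{i}" for i in range(n_nodes))
    snapshots = []
    for m in range(n_snapshots):
        mask = rng.random((n_nodes, n_nodes)) < p_edge
        np.fill_diagonal(mask, False)
        edges = {(int(i), int(j)) for i, j in zip(*np.nonzero(mask))}
        snapshots.append(Snapshot(registry, edges, label=m + 1))
    return TemporalNetwork(registry, snapshots)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160728)


@pytest.fixture
def toy_network() -> TemporalNetwork:
    """A small 4-snapshot directed network with varied edge configurations."""
    return TemporalNetwork.from_edge_lists(
        ["a", "b", "c", "d"],
        [
            [("a", "b"), ("a", "c"), ("c", "d")],
            [("a", "b"), ("d", "c"), ("b", "c")],
            [("a", "b"), ("d", "c")],
            [("a", "b"), ("a", "c"), ("d", "c")],
        ],
    )
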