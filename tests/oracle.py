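"""Naive reference implementation of the overlap equations.

Works directly on dense 0/1 adjacency matrices with explicit triple loops,
independent of the library's set-based code path, so library results can be
cross-checked against a literal transcription of the defining formulas.
"""

from __future__ import annotations

import math

import numpy as np

from temporalcorr import Direction, Snapshot, TemporalNetwork


def dense_adjacency(snapshot: Snapshot, direction: str) -> np.ndarray:
    n = len(snapshot.registry)
    a = np.zeros((n, n), dtype=int)
    for i, j in snapshot.edges:
        a[i, j] = 1
    d = Direction.coerce(direction)
    if d is Direction.IN:
        return a.T.copy()
    if d is Direction.UNDIRECTED:
        return ((a + a.T) > 0).astype(int)
    return a


def naive_node_overlap(a1: np.ndarray, a2: np.ndarray, i: int) -> float:
    num = 0.0
    for j in range(a1.shape[0]):
        num += a1[i, j] * a2[i, j]
    d1 = sum(a1[i, j] for j in range(a1.shape[0]))
    d2 = sum(a2[i, j] for j in range(a2.shape[0]))
    if d1 == 0 or d2 == 0:
        return 0.0
    return num / math.sqrt(d1 * d2)


def naive_active(a: np.ndarray) -> int:
    return sum(1 for i in range(a.shape[0]) if a[i].sum() > 0)


def naive_transition_overlap(a1: np.ndarray, a2: np.ndarray) -> float:
    denom = max(naive_active(a1), naive_active(a2))
    if denom == 0:
        return 0.0
    total = 0.0
    for i in range(a1.shape[0]):
        total += naive_node_overlap(a1, a2, i)
    return total / denom


def naive_temporal_correlation(
    network: TemporalNetwork, direction: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Return (C, per-transition C_m, per-node C_i) via explicit loops."""
    mats = [dense_adjacency(s, direction) for s in network.snapshots]
    m = len(mats)
    n = mats[0].shape[0]
    per_transition = np.array(
        [naive_transition_overlap(mats[k], mats[k + 1]) for k in range(m - 1)]
    )
    per_node = np.array(
        [
            sum(naive_node_overlap(mats[k], mats[k + 1], i) for k in range(m - 1))
            / (m - 1)
            for i in range(n)
        ]
    )
    return float(per_transition.mean()), per_transition, per_node
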