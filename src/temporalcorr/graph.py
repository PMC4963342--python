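"""Core data model: node registry, directed snapshots and temporal networks.

A temporal network is an ordered sequence of unweighted, directed graph
snapshots over one shared node universe.  Every snapshot can be read through
three directional *views* of its adjacency structure:

* ``out`` — row *i* lists the successors of node *i* (the original adjacency
  matrix; in a trade network, the purchasers a supplier ships to),
* ``in`` — row *i* lists the predecessors of node *i* (the transposed
  adjacency matrix; the suppliers a purchaser buys from),
* ``undirected`` — edge direction is ignored; row *i* is the union of
  successors and predecessors.

These views are the basis of the directed temporal correlation coefficients
computed in :mod:`temporalcorr.metrics`.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Direction",
    "NodeRegistry",
    "Snapshot",
    "TemporalNetwork",
    "view",
    "active_count",
    "reverse",
]


class Direction(str, Enum):
    """Directional view of a snapshot's adjacency structure."""

    UNDIRECTED = "undirected"
    IN = "in"
    OUT = "out"

    @classmethod
    def coerce(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown direction {value!r}; expected one of "
                f"{[d.value for d in cls]}"
            ) from None


class NodeRegistry:
    """Stable label ↔ index assignment for the node universe of a network.

    The registry fixes N, the total number of nodes, over the whole
    observation period.  Index assignment never changes for the lifetime of
    a :class:`TemporalNetwork`, so per-node results from different window
    lengths or directions refer to the same farms/individuals.
    """

    __slots__ = ("_labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        if not labels:
            raise ValueError("a node registry needs at least one node")
        index = {lab: i for i, lab in enumerate(labels)}
        if len(index) != len(labels):
            raise ValueError("node labels must be unique")
        self._labels = labels
        self._index = index

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label {label!r}") from None

    def label(self, i: int) -> str:
        return self._labels[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NodeRegistry) and self._labels == other._labels

    def __hash__(self) -> int:
        return hash(self._labels)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NodeRegistry(N={len(self)})"


class Snapshot:
    """One time window's unweighted, directed adjacency over the registry.

    Edges are stored as ordered index pairs ``(i, j)`` meaning *i → j*.
    Self-loops are dropped silently at construction (a node trading with
    itself carries no between-node persistence information) and parallel
    contacts collapse to a single edge.
    """

    __slots__ = ("registry", "edges", "label", "_rows")

    def __init__(
        self,
        registry: NodeRegistry,
        edges: Iterable[tuple[int, int]],
        label: int = 0,
    ):
        n = len(registry)
        cleaned = frozenset((i, j) for i, j in edges if i != j)
        for i, j in cleaned:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(
                    f"edge ({i}, {j}) references a node outside the registry "
                    f"(N={n})"
                )
        self.registry = registry
        self.edges = cleaned
        self.label = label
        self._rows: dict[Direction, dict[int, frozenset[int]]] = {}

    @classmethod
    def from_labels(
        cls,
        registry: NodeRegistry,
        edges: Iterable[tuple[str, str]],
        label: int = 0,
    ) -> "Snapshot":
        return cls(
            registry,
            ((registry.index(a), registry.index(b)) for a, b in edges),
            label=label,
        )

    def rows(self, direction: Direction | str) -> Mapping[int, frozenset[int]]:
        """Nonempty adjacency rows under ``direction`` (node → neighbor set)."""
        direction = Direction.coerce(direction)
        cached = self._rows.get(direction)
        if cached is not None:
            return cached
        acc: dict[int, set[int]] = {}
        if direction is Direction.OUT:
            for i, j in self.edges:
                acc.setdefault(i, set()).add(j)
        elif direction is Direction.IN:
            for i, j in self.edges:
                acc.setdefault(j, set()).add(i)
        else:
            for i, j in self.edges:
                acc.setdefault(i, set()).add(j)
                acc.setdefault(j, set()).add(i)
        rows = {i: frozenset(s) for i, s in acc.items()}
        self._rows[direction] = rows
        return rows

    def row(self, node: int, direction: Direction | str) -> frozenset[int]:
        """Neighbor set of ``node`` under ``direction`` (empty if inactive)."""
        if not (0 <= node < len(self.registry)):
            raise ValueError(
                f"node index {node} outside registry (N={len(self.registry)})"
            )
        return self.rows(direction).get(node, frozenset())

    def active_count(self, direction: Direction | str) -> int:
        """Number of active nodes: nonzero degree under the chosen view.

        ``undirected`` counts nodes touching any edge; ``in``/``out`` count
        nodes with nonzero in-/out-degree (A, A^in, A^out respectively).
        """
        return len(self.rows(direction))

    def reversed_edges(self) -> "Snapshot":
        return Snapshot(
            self.registry, ((j, i) for i, j in self.edges), label=self.label
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Snapshot)
            and self.registry == other.registry
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.registry, self.edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Snapshot(label={self.label}, edges={len(self.edges)})"


class TemporalNetwork:
    """Ordered sequence of M snapshots sharing one node registry."""

    __slots__ = ("registry", "snapshots")

    def __init__(self, registry: NodeRegistry, snapshots: Sequence[Snapshot]):
        snapshots = tuple(snapshots)
        if not snapshots:
            raise ValueError("a temporal network needs at least one snapshot")
        for s in snapshots:
            if s.registry != registry:
                raise ValueError("all snapshots must share the network registry")
        self.registry = registry
        self.snapshots = snapshots

    @classmethod
    def from_edge_lists(
        cls,
        labels: Iterable[str],
        edge_lists: Sequence[Iterable[tuple[str, str]]],
    ) -> "TemporalNetwork":
        """Convenience constructor from per-snapshot lists of label pairs."""
        registry = NodeRegistry(labels)
        snaps = [
            Snapshot.from_labels(registry, edges, label=m)
            for m, edges in enumerate(edge_lists)
        ]
        return cls(registry, snaps)

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    @property
    def n_nodes(self) -> int:
        return len(self.registry)

    def transitions(self) -> Iterator[tuple[Snapshot, Snapshot]]:
        """Consecutive snapshot pairs (t_m, t_{m+1}), m = 1 … M−1."""
        return zip(self.snapshots, self.snapshots[1:])

    def reverse(self) -> "TemporalNetwork":
        """Flip every edge (i → j becomes j → i) in every snapshot."""
        return TemporalNetwork(
            self.registry, [s.reversed_edges() for s in self.snapshots]
        )

    def __len__(self) -> int:
        return len(self.snapshots)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TemporalNetwork(N={self.n_nodes}, M={self.n_snapshots})"


def view(snapshot: Snapshot, direction: Direction | str) -> Mapping[int, frozenset[int]]:
    """Adjacency view of a snapshot: node → neighbor set under ``direction``."""
    return snapshot.rows(direction)


def active_count(snapshot: Snapshot, direction: Direction | str) -> int:
    """Number of nodes with nonzero degree under the chosen directional view."""
    return snapshot.active_count(direction)


def reverse(network: TemporalNetwork) -> TemporalNetwork:
    """Edge-reversed copy of a temporal network (registry unchanged)."""
    return network.reverse()
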