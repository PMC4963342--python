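"""Aggregate timestamped contact records into temporal-network snapshots.

The observation period of ``observation_days`` days is partitioned into
non-overlapping windows of a fixed length L: window k (1-based) covers days
(k−1)·L + 1 … k·L inclusive.  All contacts within a window collapse into one
unweighted directed snapshot.  A trailing window shorter than L — which
exists whenever L does not divide the observation period — is excluded, so
exactly ⌊observation_days / L⌋ snapshots are produced (e.g. a 1096-day span
gives 1096, 548 and 2 snapshots at window lengths 1, 2 and 548).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

from .graph import NodeRegistry, Snapshot, TemporalNetwork

__all__ = ["MovementRecord", "build_snapshots", "window_of_day"]


class MovementRecord(NamedTuple):
    """One timestamped directed contact: on ``day``, ``source`` → ``target``.

    ``day`` is a 1-based index within the observation period.
    """

    day: int
    source: str
    target: str


def window_of_day(day: int, window_length: int) -> int:
    """1-based index of the window containing ``day`` (= ⌈day / L⌉)."""
    return (day - 1) // window_length + 1


def build_snapshots(
    records: Sequence[MovementRecord] | Iterable[MovementRecord],
    window_length: int,
    observation_days: int | None = None,
) -> TemporalNetwork:
    """Aggregate movement records into a temporal network of snapshots.

    Parameters
    ----------
    records
        Timestamped directed contacts (1-based day index).
    window_length
        Aggregation window length L in days.
    observation_days
        Length of the observation period; defaults to the largest day index
        present.  Records dated outside [1, observation_days] raise.

    Notes
    -----
    The node registry covers every node appearing in any record — including
    nodes whose only contacts fall in the discarded trailing window; such
    nodes are inactive in every snapshot and contribute zero to all overlap
    sums, leaving N a property of the dataset rather than of the window
    choice.
    """
    records = list(records)
    if window_length < 1:
        raise ValueError(f"window length must be >= 1 (got {window_length})")
    if not records:
        raise ValueError("no movement records given")
    if observation_days is None:
        observation_days = max(r.day for r in records)
    if observation_days < window_length:
        raise ValueError(
            f"observation period ({observation_days} days) shorter than the "
            f"window length ({window_length} days)"
        )

    labels: dict[str, None] = {}  # insertion-ordered node universe
    for r in records:
        if not (1 <= r.day <= observation_days):
            raise ValueError(
                f"record day {r.day} outside the observation period "
                f"[1, {observation_days}] ({r.source} -> {r.target})"
            )
        labels.setdefault(str(r.source))
        labels.setdefault(str(r.target))
    registry = NodeRegistry(labels)

    n_windows = observation_days // window_length
    edges: list[set[tuple[int, int]]] = [set() for _ in range(n_windows)]
    for r in records:
        k = window_of_day(r.day, window_length)
        if k > n_windows:  # incomplete trailing window: excluded
            continue
        if r.source == r.target:
            continue
        edges[k - 1].add((registry.index(r.source), registry.index(r.target)))

    snapshots = [
        Snapshot(registry, e, label=k + 1) for k, e in enumerate(edges)
    ]
    return TemporalNetwork(registry, snapshots)
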