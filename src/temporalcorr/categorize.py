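"""Categorize per-node average overlaps and summarize them by group.

Node-level average topological overlaps C_i live in [0, 1]; to compare their
distribution across groups (e.g. farm types in a trade network) the values
are binned into six categories:

    0: C_i = 0        1: 0 < C_i ≤ 0.2    2: 0.2 < C_i ≤ 0.4
    3: 0.4 < C_i ≤ 0.6    4: 0.6 < C_i ≤ 0.8    5: 0.8 < C_i ≤ 1

Boundary values belong to the lower category (intervals open below, closed
above); exact zero — e.g. a node with no outgoing edges in any snapshot —
is its own category.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_LABELS",
    "categorize",
    "categorize_value",
    "frequency_table",
    "summarize_by_group",
]

#: upper bin edges of categories 1–5
_UPPER_EDGES = (0.2, 0.4, 0.6, 0.8)

CATEGORY_LABELS = (0, 1, 2, 3, 4, 5)


def categorize_value(value: float) -> int:
    """Category (0–5) of a single average-overlap value."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"overlap value {value} outside [0, 1]")
    if value == 0.0:
        return 0
    return int(np.searchsorted(_UPPER_EDGES, value, side="left")) + 1


def categorize(values: Mapping[str, float]) -> dict[str, int]:
    """Map every node to its overlap category."""
    return {node: categorize_value(v) for node, v in values.items()}


def _validate_groups(
    values: Mapping[str, float], groups: Mapping[str, str]
) -> None:
    if not values:
        raise ValueError("no values to tabulate")
    missing = [node for node in values if node not in groups]
    if missing:
        raise ValueError(
            f"{len(missing)} node(s) have no group label, e.g. {missing[0]!r}"
        )


def frequency_table(
    values: Mapping[str, float], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Percentage of nodes per category, one row per group.

    Rows are groups, columns the six categories; each row sums to 100.
    """
    _validate_groups(values, groups)
    cats = categorize(values)
    df = pd.DataFrame(
        {
            "group": [groups[n] for n in values],
            "category": [cats[n] for n in values],
        }
    )
    counts = (
        df.groupby("group")["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORY_LABELS), fill_value=0)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns.name = "category"
    return pct


def summarize_by_group(
    values: Mapping[str, float], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Mean and (min, max) range of the values per group."""
    _validate_groups(values, groups)
    df = pd.DataFrame(
        {
            "group": [groups[n] for n in values],
            "value": [values[n] for n in values],
        }
    )
    out = df.groupby("group")["value"].agg(mean="mean", min="min", max="max")
    return out
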