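"""CSV readers and writers for movement records, snapshots and results.

Two input dialects are accepted for movement files and auto-detected per
file: calendar dates (ISO ``YYYY-MM-DD``, mapped to 1-based day indices
relative to the earliest date in the file) or plain integer day indices.
Mixing both in one file is an error.  All files are UTF-8, comma-separated,
with a header row; node labels containing commas are rejected rather than
quoted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .graph import NodeRegistry, Snapshot, TemporalNetwork
from .metrics import OverlapResult
from .windowing import MovementRecord

__all__ = [
    "MovementData",
    "read_movements",
    "read_snapshot_edgelists",
    "write_snapshot_edgelists",
    "write_results",
    "write_node_overlaps",
]

logger = logging.getLogger(__name__)

_DATE_ALIASES = ("date", "day")
_SOURCE_ALIASES = ("source", "supplier", "from")
_TARGET_ALIASES = ("target", "purchaser", "to")
_ISO_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_INT_RE = re.compile(r"^\d+$")


@dataclass(frozen=True)
class MovementData:
    """Parsed movement file: records, node universe and period length."""

    records: tuple[MovementRecord, ...]
    labels: tuple[str, ...]
    observation_days: int
    dropped_self_loops: int


def _find_column(columns: Sequence[str], aliases: Sequence[str], what: str) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise ValueError(
        f"movement file is missing a {what} column "
        f"(looked for {'/'.join(aliases)}; found {list(columns)})"
    )


def _days_from_dates(raw: pd.Series) -> pd.Series:
    """Map the date column to 1-based day indices, detecting the dialect."""
    text = raw.astype(str).str.strip()
    is_int = text.str.match(_INT_RE)
    is_iso = text.str.match(_ISO_RE)
    if is_int.all():
        return text.astype(int)
    if is_iso.all():
        dates = pd.to_datetime(text, format="%Y-%m-%d")
        return (dates - dates.min()).dt.days + 1
    bad = text[~(is_int | is_iso)]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"malformed date {bad.iloc[0]!r} in row {row + 2} "
            "(expected YYYY-MM-DD or an integer day index)"
        )
    raise ValueError(
        "movement file mixes integer day indices and calendar dates; "
        "use one dialect per file"
    )


def read_movements(path: str | Path) -> MovementData:
    """Read a movement CSV into timestamped directed contact records.

    Expects columns for the movement date (``date``/``day``), the supplier
    (``source``/``supplier``/``from``) and the purchaser
    (``target``/``purchaser``/``to``); any further columns (batch size,
    animal type, …) are ignored.  Self-loops are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"movement file {path} contains no records")
    date_col = _find_column(df.columns, _DATE_ALIASES, "date")
    src_col = _find_column(df.columns, _SOURCE_ALIASES, "source")
    tgt_col = _find_column(df.columns, _TARGET_ALIASES, "target")

    days = _days_from_dates(df[date_col])
    sources = df[src_col].astype(str).str.strip()
    targets = df[tgt_col].astype(str).str.strip()
    for col, name in ((sources, src_col), (targets, tgt_col)):
        if (col == "").any():
            row = col[col == ""].index[0]
            raise ValueError(f"empty {name!r} label in row {row + 2}")
        if col.str.contains(",").any():
            row = col[col.str.contains(",")].index[0]
            raise ValueError(
                f"node label {col.loc[row]!r} in row {row + 2} contains a "
                "comma; such labels are not supported"
            )

    keep = sources != targets
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d self-loop record(s) from %s", dropped, path)

    records = tuple(
        MovementRecord(int(d), s, t)
        for d, s, t in zip(days[keep], sources[keep], targets[keep])
    )
    if not records:
        raise ValueError(f"movement file {path} has no non-self-loop records")
    labels: dict[str, None] = {}
    for r in records:
        labels.setdefault(r.source)
        labels.setdefault(r.target)
    return MovementData(
        records=records,
        labels=tuple(labels),
        observation_days=int(days.max()),
        dropped_self_loops=dropped,
    )


def _snapshot_sort_key(path: Path) -> tuple[int, str]:
    m = re.search(r"(\d+)", path.stem)
    return (int(m.group(1)) if m else -1, path.name)


def read_snapshot_edgelists(path: str | Path) -> TemporalNetwork:
    """Read a pre-built snapshot sequence into a temporal network.

    ``path`` is either a directory of per-snapshot CSV files (each with
    ``source,target`` columns; snapshot order given by the integer embedded
    in each filename) or a single CSV with ``snapshot,source,target``
    columns.  Duplicate edge rows collapse to one edge.
    """
    path = Path(path)
    per_snapshot: list[list[tuple[str, str]]] = []
    if path.is_dir():
        files = sorted(path.glob("*.csv"), key=_snapshot_sort_key)
        if not files:
            raise ValueError(f"no snapshot CSV files found in {path}")
        for f in files:
            df = pd.read_csv(f, dtype=str, keep_default_na=False)
            src = _find_column(df.columns, _SOURCE_ALIASES, "source")
            tgt = _find_column(df.columns, _TARGET_ALIASES, "target")
            per_snapshot.append(list(zip(df[src], df[tgt])))
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if df.empty:
            raise ValueError(f"snapshot file {path} contains no edges")
        snap_col = _find_column(df.columns, ("snapshot", "window", "m"), "snapshot")
        src = _find_column(df.columns, _SOURCE_ALIASES, "source")
        tgt = _find_column(df.columns, _TARGET_ALIASES, "target")
        df["_m"] = df[snap_col].astype(int)
        for _, chunk in df.sort_values("_m").groupby("_m", sort=True):
            per_snapshot.append(list(zip(chunk[src], chunk[tgt])))
    if not per_snapshot:
        raise ValueError(f"no snapshots found at {path}")

    labels: dict[str, None] = {}
    for edges in per_snapshot:
        for a, b in edges:
            labels.setdefault(a)
            labels.setdefault(b)
    if not labels:
        raise ValueError(f"snapshots at {path} contain no edges")
    registry = NodeRegistry(labels)
    snapshots = [
        Snapshot.from_labels(registry, edges, label=m + 1)
        for m, edges in enumerate(per_snapshot)
    ]
    return TemporalNetwork(registry, snapshots)


def write_snapshot_edgelists(network: TemporalNetwork, directory: str | Path) -> None:
    """Write one ``snapshot_<m>.csv`` edge list per snapshot."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = len(str(network.n_snapshots))
    for m, snap in enumerate(network.snapshots, start=1):
        rows = sorted(
            (network.registry.label(i), network.registry.label(j))
            for i, j in snap.edges
        )
        pd.DataFrame(rows, columns=["source", "target"]).to_csv(
            directory / f"snapshot_{m:0{width}d}.csv", index=False
        )


def write_results(result: OverlapResult | pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV (floats at 6 decimal places).

    An :class:`OverlapResult` becomes a long-format table with one row per
    transition (``quantity=transition``, keyed by m) plus one ``network``
    row; per-node values are written separately by
    :func:`write_node_overlaps`.  DataFrames (sweep tables, category tables,
    group summaries) are written as-is with the index preserved.
    """
    path = Path(path)
    if isinstance(result, OverlapResult):
        rows = [
            ("transition", m + 1, v)
            for m, v in enumerate(result.per_transition)
        ]
        rows.append(("network", "", result.network))
        df = pd.DataFrame(rows, columns=["quantity", "key", "value"])
        df.to_csv(path, index=False, float_format="%.6f")
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path, float_format="%.6f")
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")


def write_node_overlaps(result: OverlapResult, path: str | Path) -> None:
    """Write the per-node average overlaps keyed by node label."""
    df = result.per_node.rename_axis("node").reset_index()
    df.to_csv(Path(path), index=False, float_format="%.6f")
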