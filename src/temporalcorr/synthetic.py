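"""Synthetic pig-trade temporal networks with periodic directed contacts.

The generator emulates the structure of a pork-supply-chain contact network:
four farm types with directed trade flowing downstream —

* multipliers supply breeding gilts to farrowing and farrow-to-finishing
  farms,
* farrowing farms supply piglets to finishing farms,
* finishing and farrow-to-finishing farms ship only to abattoirs, which are
  excluded from the network, so these end-of-chain farms emit no outgoing
  records at all.

Each purchaser keeps a small fixed pool of suppliers (health-protection
practice favours few suppliers), and each supplier–purchaser relationship
fires periodically: one contact every ``contact_period_days`` with a uniform
jitter of ±⌊period/8⌋ days around the scheduled grid, surviving from one
cycle to the next with probability ``partner_stability``.  The jitter keeps
persistence imperfect, as in real trade data where coefficients peak well
below 1.  ``movements_target`` caps the total record count: whole
relationships are retained greedily in random order until the target is
reached, preserving the periodic structure of every retained relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import Direction
from .metrics import window_sweep
from .windowing import MovementRecord

__all__ = [
    "TradeConfig",
    "FARM_TYPES",
    "generate",
    "farm_types",
    "period_recovery_check",
]

FARM_TYPES = ("multiplier", "farrowing", "finishing", "farrow_to_finishing")

#: relationship classes: (supplier type, purchaser type)
RELATIONSHIP_CLASSES = (
    ("multiplier", "farrowing"),
    ("multiplier", "farrow_to_finishing"),
    ("farrowing", "finishing"),
)

_DEFAULT_PERIODS = {
    ("multiplier", "farrowing"): 88,
    ("multiplier", "farrow_to_finishing"): 88,
    ("farrowing", "finishing"): 62,
}


@dataclass(frozen=True)
class TradeConfig:
    """Configuration of the synthetic trade network.

    Defaults mirror a producer-community pig-trade dataset: 29 multipliers,
    34 farrowing, 153 finishing and 267 farrow-to-finishing farms trading
    ~4635 movements over a 1096-day observation period, with contact periods
    of roughly three months for breeding-stock deliveries and two months for
    piglet deliveries.
    """

    n_multiplier: int = 29
    n_farrowing: int = 34
    n_finishing: int = 153
    n_farrow_to_finishing: int = 267
    observation_days: int = 1096
    contact_period_days: int | Mapping[tuple[str, str], int] | None = None
    movements_target: int = 4635
    partner_stability: float = 0.9
    suppliers_per_purchaser: tuple[int, int] = (1, 3)
    seed: int = 0

    def counts(self) -> dict[str, int]:
        return {
            "multiplier": self.n_multiplier,
            "farrowing": self.n_farrowing,
            "finishing": self.n_finishing,
            "farrow_to_finishing": self.n_farrow_to_finishing,
        }

    def periods(self) -> dict[tuple[str, str], int]:
        p = self.contact_period_days
        if p is None:
            return dict(_DEFAULT_PERIODS)
        if isinstance(p, int):
            return {cls: p for cls in RELATIONSHIP_CLASSES}
        return {cls: int(p[cls]) for cls in RELATIONSHIP_CLASSES if cls in p}

    def validate(self) -> None:
        counts = self.counts()
        if any(v < 0 for v in counts.values()):
            raise ValueError("farm counts must be non-negative")
        if sum(counts.values()) < 2:
            raise ValueError("need at least 2 farms in total")
        if not 0.0 <= self.partner_stability <= 1.0:
            raise ValueError("partner_stability must lie in [0, 1]")
        lo, hi = self.suppliers_per_purchaser
        if not 1 <= lo <= hi:
            raise ValueError("suppliers_per_purchaser must satisfy 1 <= lo <= hi")
        for cls, period in self.periods().items():
            if not 1 <= period <= self.observation_days:
                raise ValueError(
                    f"contact period {period} for {cls} outside "
                    f"[1, {self.observation_days}]"
                )
        feasible = any(
            counts[sup] > 0 and counts[buy] > 0
            for sup, buy in self.periods()
        )
        if not feasible:
            raise ValueError(
                "infeasible config: no relationship class has both a "
                "supplier and a purchaser population"
            )


def farm_types(config: TradeConfig) -> dict[str, str]:
    """Node label → farm type for every farm in the configuration."""
    out: dict[str, str] = {}
    for ftype, count in config.counts().items():
        for k in range(1, count + 1):
            out[f"{ftype}_{k:03d}"] = ftype
    return out


def _relationship_schedule(
    rng: np.random.Generator,
    period: int,
    observation_days: int,
    stability: float,
) -> list[int]:
    """Contact days of one supplier–purchaser relationship."""
    jitter = period // 8
    phase = int(rng.integers(1, period + 1))
    days: list[int] = []
    cycle = 0
    while True:
        scheduled = phase + cycle * period
        if scheduled > observation_days:
            break
        if cycle > 0 and rng.random() >= stability:
            break  # relationship dissolves before this cycle
        day = scheduled
        if jitter > 0:
            day += int(rng.integers(-jitter, jitter + 1))
        day = min(max(day, 1), observation_days)
        days.append(day)
        cycle += 1
    return days


def generate(config: TradeConfig | None = None, **overrides) -> list[MovementRecord]:
    """Generate a synthetic movement-record stream (deterministic per seed).

    Returns records sorted by day, then source, then target.
    """
    if config is None:
        config = TradeConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a TradeConfig or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts()
    nodes_by_type = {
        ftype: [f"{ftype}_{k:03d}" for k in range(1, counts[ftype] + 1)]
        for ftype in FARM_TYPES
    }

    # each purchaser draws a small fixed pool of suppliers at simulation start
    lo, hi = config.suppliers_per_purchaser
    relationships: list[tuple[str, str, int]] = []
    for (sup_type, buy_type), period in config.periods().items():
        suppliers = nodes_by_type[sup_type]
        purchasers = nodes_by_type[buy_type]
        if purchasers and not suppliers:
            raise ValueError(
                f"infeasible config: {buy_type} farms have no {sup_type} "
                "suppliers"
            )
        for buyer in purchasers:
            k = int(rng.integers(lo, min(hi, len(suppliers)) + 1))
            pool = rng.choice(len(suppliers), size=k, replace=False)
            for idx in sorted(pool):
                relationships.append((suppliers[idx], buyer, period))

    if not relationships:
        raise ValueError("infeasible config: no trade relationships possible")

    schedules = [
        (
            supplier,
            buyer,
            _relationship_schedule(
                rng, period, config.observation_days, config.partner_stability
            ),
        )
        for supplier, buyer, period in relationships
    ]

    # honor movements_target: keep whole relationships, in random order,
    # until the target count is reached
    order = rng.permutation(len(schedules))
    records: list[MovementRecord] = []
    for idx in order:
        if len(records) >= config.movements_target:
            break
        supplier, buyer, days = schedules[idx]
        records.extend(MovementRecord(d, supplier, buyer) for d in days)

    records.sort()
    return records


def period_recovery_check(
    records: Sequence[MovementRecord],
    true_period: int,
    lengths: Sequence[int],
    observation_days: int | None = None,
    direction: Direction | str = Direction.OUT,
) -> int:
    """Window-sweep argmax on data with a known contact period.

    With stable periodic relationships the coefficient-maximizing window
    length should fall within one sweep step of ``true_period``; the caller
    asserts that.  Returns the recovered length.
    """
    if observation_days is None:
        observation_days = max(r.day for r in records)
    result = window_sweep(records, lengths, observation_days, direction)
    if result.best_length is None:
        raise ValueError("sweep produced no defined coefficient")
    return result.best_length
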