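"""Per-node overlap categories by farm type on synthetic trade data.

Computes the per-node average outgoing topological overlap C_i^out on a
synthetic pork-supply-chain network aggregated into 90-day windows — close
to the ~88/62-day contact periods of the generated trade relationships —
then
tabulates the distribution over six categories (0, (0,0.2], ..., (0.8,1])
per farm type.  Farms at the end of the chain (finishing and
farrow-to-finishing) never ship — abattoirs are excluded — so their
C_i^out is structurally zero and they land entirely in category 0.
"""

from temporalcorr import (
    Direction,
    TradeConfig,
    build_snapshots,
    farm_types,
    frequency_table,
    generate,
    summarize_by_group,
    temporal_correlation,
)

cfg = TradeConfig(seed=0)
records = generate(cfg)
net = build_snapshots(records, 90, cfg.observation_days)
print(f"{len(records)} movements, {net.n_nodes} farms, "
      f"{net.n_snapshots} ninety-day snapshots\n")

per_node = temporal_correlation(net, Direction.OUT).per_node
groups = farm_types(cfg)
values = {n: float(v) for n, v in per_node.items()}
groups = {n: groups[n] for n in values}

print("percentage of farms per C_i^out category (columns 0..5):")
print(frequency_table(values, groups).to_string(float_format=lambda v: f"{v:5.1f}"))
print("\nmean and range of C_i^out per farm type:")
print(summarize_by_group(values, groups).to_string(float_format=lambda v: f"{v:.3f}"))
print(
    "\nWith windows matching the contact period, the supplying farm types "
    "\n(multipliers, farrowing farms) show high outgoing persistence — most "
    "\nland in category 5 — while end-of-chain farms sit entirely in "
    "category 0."
)
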