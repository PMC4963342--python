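"""Recover the contact period of a synthetic trade network by window sweep.

Generates a periodic pig-trade-like movement stream (suppliers ship to fixed
purchasers roughly every 10 days) and sweeps the aggregation window length.
The temporal correlation coefficient peaks where windows match the contact
period: consecutive snapshots then hold near-identical edge sets.
"""

from temporalcorr import Direction, TradeConfig, generate, window_sweep

cfg = TradeConfig(
    n_multiplier=5,
    n_farrowing=6,
    n_finishing=20,
    n_farrow_to_finishing=30,
    observation_days=300,
    contact_period_days=10,
    movements_target=3000,
    partner_stability=0.9,
    seed=1,
)
records = generate(cfg)
print(f"generated {len(records)} movements over {cfg.observation_days} days "
      f"(true contact period: 10 days)\n")

result = window_sweep(records, range(2, 31, 2), cfg.observation_days, Direction.OUT)
print(result.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    f"\nC^out is maximal at a window length of {result.best_length} days — "
    "within one sweep step\nof the 10-day contact period used to generate "
    "the data."
)
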