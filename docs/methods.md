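# Methods

## Model and procedure

A temporal network is an ordered sequence of M unweighted, directed
snapshots over a fixed registry of N nodes. The node universe is global: a
node belongs to the registry if it appears in **any** record of the dataset,
including records that fall into a discarded trailing window. Inactive nodes
contribute zero to every overlap sum, so this choice leaves the coefficients
unchanged while keeping N a property of the dataset rather than of the
window length. Self-loops are dropped at construction and parallel contacts
within a window collapse to a single edge.

The temporal correlation coefficient is computed in three steps (per-node
overlap between consecutive snapshots → per-transition average → network
mean), parameterized by a *direction*:

* `out` — rows of the original adjacency (successor sets), active count
  A^out = nodes with nonzero out-degree;
* `in` — rows of the transposed adjacency (predecessor sets), active count
  A^in;
* `undirected` — rows of the symmetrized adjacency, active count = nodes
  with nonzero degree.

All three variants share one code path; the direction only changes which
row view and which active count are used.

### Normalization

The per-transition average divides the summed node overlaps by
max[A(t_m), A(t_{m+1})], the larger active population of the two snapshots.
This keeps transitions between sparse snapshots comparable in networks where
most nodes are silent most of the time. The older 1/N normalization from the
undirected literature is available via `normalization="nodes"`
(default off) for comparability with earlier work.

### Zero conventions

* A node with an empty row in either snapshot of a transition has an
  undefined overlap ratio; the value is defined as 0. The rule is applied
  symmetrically to all three directions (its practical origin is nodes
  without outgoing edges, such as end-of-chain farms once abattoirs are
  excluded).
* A transition between two snapshots that are both empty under the chosen
  view has max active count 0; its per-transition overlap is defined as 0
  (no edge persists because there are no edges).

### Windowing

An observation period of D days is split into consecutive windows of length
L: window k covers days (k−1)·L+1 … k·L (1-based, closed). Exactly ⌊D/L⌋
complete windows are kept; a shorter trailing window is excluded because its
thinner edge set would bias the final transition downward. A 1096-day span
therefore yields 1096, 548, 365 and 2 snapshots at L = 1, 2, 3 and 548.
Calendar-dated input is converted to day indices relative to the earliest
date in the file (day 1) before windowing.

### Convergence experiment

To exhibit the coefficient's behaviour as persistence becomes perfect, the
network is extended to a target length (default 100) by appending copies of
its final snapshot. Each appended transition joins identical snapshots and
contributes an overlap of exactly 1, so the series

    C(L) = (S + (L − M)) / (L − 1),   S = sum of the original M−1 transitions

is non-decreasing over the appended range and converges to 1 from below,
with 1 − C(100) < (M−1)/99. The implementation computes the appended
transition's overlap rather than assuming 1, and the closed form is used
only as an independent check in the tests.

### Categories

Per-node average overlaps are binned into six categories: exactly 0, then
five half-open intervals (0, 0.2], (0.2, 0.4], (0.4, 0.6], (0.6, 0.8],
(0.8, 1]. Boundary values belong to the lower category. The exact-zero
category isolates structural zeros (nodes that are never active under the
chosen view) from genuinely low persistence. Group frequency tables report
percentages per group that sum to 100; group summaries report mean and
(min, max).

## Synthetic trade-network generator

The generator emulates a pork-supply-chain movement registry: four farm
types (29 multipliers, 34 farrowing, 153 finishing, 267 farrow-to-finishing
by default) trading over a 1096-day observation period with a target of
4635 movement records. Directed trade flows strictly downstream — multiplier
→ farrowing / farrow-to-finishing (breeding-gilt replacement, default period
88 days) and farrowing → finishing (piglet batches, default period 62 days).
Finishing and farrow-to-finishing farms ship only to abattoirs, which are
outside the network, so they emit no outgoing records at all; their
C_i^out is structurally zero, which the tests assert.

Mechanics, with defaults and rationale:

* **Supplier pools.** Each purchaser draws 1–3 suppliers once at simulation
  start (herd-health practice favours few, constant suppliers).
* **Schedules.** Each supplier–purchaser relationship fires at
  phase + k·period with independent uniform jitter of ±⌊period/8⌋ days
  around the fixed grid. The jitter keeps persistence imperfect, as in real
  registries where coefficients peak well below 1.
* **Stability.** A relationship survives from one scheduled cycle to the
  next with probability `partner_stability` (default 0.9) and dissolves
  permanently on failure.
* **Movement target.** Whole relationships are retained greedily in random
  order until the cumulative record count reaches `movements_target`;
  retaining whole relationships preserves the periodic structure of
  everything kept. The realized count overshoots the target by at most one
  relationship's contacts (within a few per mille at default scale).
* **Determinism.** A single `numpy` generator seeded from `seed` drives all
  draws in a fixed iteration order, so identical configurations reproduce
  identical record streams.

What the generator does **not** emulate: batch sizes, age groups, seasonal
or holiday effects, farm turnover (entry/exit), mixed per-farm periods, or
any disease process. Passing tests on this data therefore demonstrate the
correctness and the qualitative behaviour of the estimator (period recovery,
structural zeros, directional asymmetry), not quantitative agreement with
any real trade registry.

On sweep resolution: with periodic relationships the coefficient-maximizing
window length lands within one sweep step of the true period, typically one
step **above** it, because a window slightly longer than the period absorbs
the scheduling jitter. Tests assert recovery within one step accordingly.

## Numerical choices

* Per-transition sums use `math.fsum`, whose correctly rounded result is
  independent of summation order. This makes the transpose duality —
  C^in of a network equals C^out of its edge-reversed copy — hold bit-exactly,
  not just to tolerance, and the tests assert exact equality.
* Range checks on [0, 1] allow 1e-12 slack; no clipping is applied.
* The oracle-equivalence tests compare the set-based implementation against
  a literal dense-matrix triple-loop transcription of the defining formulas
  at 1e-12 absolute tolerance, over all 64 two-node three-snapshot networks
  exhaustively plus several hundred random networks.
* Window sweeps report lengths that leave fewer than two complete windows
  as NaN (undefined) rather than dropping the row, so the requested grid is
  always visible in the output.

## Problem sizes

The default test and acceptance workloads use 1000 random networks with
N ≤ 20 and M ≤ 10 for range checks, 100 networks for duality, ~360 networks
for oracle equivalence, and a scaled trade simulation (61 farms, 300 days,
10-day period, ~1100 movements) for period recovery; the full suite runs in
a few seconds. The generator's default scale (483 farms, 1096 days, ~4635
movements) is used for the structural-zero and reproducibility checks and
for the examples.

## Known limitations

* The coefficient compares only consecutive snapshots; longer-range
  recurrence (e.g. contacts returning every second window) registers as
  churn. The window sweep partly compensates by rescaling time.
* The undirected coefficient is not provably ≥ the directed ones; the
  package computes all three and asserts no ordering.
* Snapshots are dense in node space but sparse in edges; the set-based
  implementation targets registries of up to a few thousand nodes and is
  not tuned for dense graphs.
* Overlapping (sliding) windows and continuous-time representations are out
  of scope.
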