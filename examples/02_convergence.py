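"""Convergence of the coefficients under identical snapshot extension.

Repeatedly appends the final snapshot of a small network until the sequence
is 100 snapshots long.  Every appended transition joins two identical
snapshots and contributes a per-transition overlap of exactly 1, so all
three coefficients climb towards 1 from below — a sanity check that the
measure behaves like a persistence probability.
"""

from temporalcorr import TemporalNetwork, convergence_series

net = TemporalNetwork.from_edge_lists(
    ["a", "b", "c", "d"],
    [
        [("a", "b"), ("a", "c"), ("c", "d")],
        [("a", "b"), ("d", "c"), ("b", "c")],
        [("a", "b"), ("d", "c")],
        [("a", "b"), ("a", "c"), ("d", "c")],
    ],
)

print("length   C        C^in     C^out")
series = {
    d: convergence_series(net, 100, d) for d in ("undirected", "in", "out")
}
for k, length in enumerate(range(net.n_snapshots, 101)):
    if length in (4, 5, 10, 25, 50, 100):
        row = "  ".join(f"{series[d][k]:.4f}" for d in series)
        print(f"{length:>6}   {row}")

print(
    "\nAll three series are non-decreasing and bounded by 1; after 96"
    "\nappended copies only the initial churn of the first 3 transitions"
    "\nkeeps them below 1 (gap < (M-1)/99)."
)
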