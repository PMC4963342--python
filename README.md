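# temporalcorr

Temporal correlation coefficients for **directed** contact networks.

When a dynamic system — livestock trade, social contacts, disease-relevant
movements — is studied as a network, the usual shortcut is to aggregate all
contacts over the observation period into one static graph. Whether that
aggregation is faithful depends on how stable the edge configuration is over
time. The *temporal correlation coefficient* C quantifies this: it is the
overall average probability for an edge to persist between two consecutive
snapshots of the temporal network. This package computes C together with its
directed counterparts C<sup>in</sup> and C<sup>out</sup>, which are essential
whenever edge direction carries meaning (who supplies whom, who infects
whom): a farm can have perfectly stable suppliers and completely churning
purchasers, and the undirected coefficient would hide the difference.

It is aimed at epidemiologists and network scientists working with
timestamped directed contact records such as animal-movement registries.

## The statistic

For a temporal network of M snapshots over N nodes with unweighted adjacency
matrices a(t_m), the topological overlap of node *i* between consecutive
snapshots is

    C_i(t_m, t_{m+1}) = Σ_j a_ij(t_m) a_ij(t_{m+1})
                        / sqrt( Σ_j a_ij(t_m) · Σ_j a_ij(t_{m+1}) )

— the neighbors node *i* keeps, normalized by the geometric mean of its two
degrees. Averaging over nodes with the *max-active* normalization gives the
per-transition overlap

    C_m = (1 / max[A(t_m), A(t_{m+1})]) Σ_{i=1}^{N} C_i(t_m, t_{m+1}),

where A(t) counts nodes with nonzero degree, and the network coefficient is
C = (1/(M−1)) Σ_m C_m. Per-node averages C_i over all transitions support
node-level comparisons.

The directed variants run the same three steps on a directional view of the
adjacency:

* **C<sup>out</sup>** — original matrix; rows are purchaser (successor)
  sets; normalization by A<sup>out</sup>, the count of nodes with nonzero
  out-degree.
* **C<sup>in</sup>** — transposed matrix; rows are supplier (predecessor)
  sets; normalization by A<sup>in</sup>.
* **C (undirected)** — symmetrized matrix; direction ignored.

A node with an empty row in either snapshot (e.g. a finishing farm that
never ships once abattoirs are excluded) has an undefined ratio; its overlap
is set to zero. All quantities lie in [0, 1]; two identical nonempty
snapshots give C_m = 1 exactly.

## Worked example

`examples/01_toy_network_coefficients.py` builds a 4-node, 4-snapshot
directed network and prints:

```
network: N=4 nodes, M=4 snapshots

C^undirected = 0.8119   (per transition: 0.7286, 0.8536, 0.8536)
C^in         = 0.6801   (per transition: 0.3333, 0.8536, 0.8536)
C^out        = 0.5853   (per transition: 0.2357, 0.6667, 0.8536)
```

The edge a→b persists through all four snapshots, so every coefficient is
well above zero; the directed coefficients are lower than the undirected one
because ignoring direction doubles the chance of finding a persisting
contact. The per-node outgoing values single out the nodes with stable
purchaser sets (C_i^out(a) = 0.80) from those that never ship
(C_i^out(b) = 0).

The other examples demonstrate the convergence experiment (extending a
network with copies of its last snapshot drives all coefficients to 1 from
below), recovery of a known trade period from the window-length sweep, and
per-farm-type category tables on synthetic pig-trade data. Each is run as
`python examples/<name>.py`.

## Command line

A thin CLI wraps the library for pipeline use:

```sh
temporalcorr simulate --seed 1 --output moves.csv --groups-output types.csv
temporalcorr sweep --input moves.csv --sweep 10:120:2 --direction all --output sweep.csv
temporalcorr tcc --input moves.csv --window-length 88 --output result
temporalcorr convergence --input snaps_dir/ --target-length 100 --output conv.csv
temporalcorr categorize --values result.out.nodes.csv --groups types.csv --output cats
```

Inputs are movement CSVs (`day|date, source, target`, extra columns
ignored; ISO dates or integer day indices) or directories of per-snapshot
edge lists. Progress and counts go to stderr; results go to files.

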