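from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from temporalcorr import (
    Direction,
    NodeRegistry,
    Snapshot,
    TemporalNetwork,
    convergence_series,
    node_average_overlap,
    node_overlap,
    reverse,
    temporal_correlation,
    transition_overlap,
    window_sweep,
    MovementRecord,
)
from conftest import random_network
from oracle import naive_temporal_correlation

DIRECTIONS = list(Direction)


def snapshots_from_out_rows(*rows_per_snapshot):
    """Build a network where snapshot m has out-rows given as {node: targets}."""
    labels = "abcdefgh"
    registry = NodeRegistry(labels)
    snaps = []
    for m, rows in enumerate(rows_per_snapshot):
        edges = {
            (labels.index(i), labels.index(j))
            for i, targets in rows.items()
            for j in targets
        }
        snaps.append(Snapshot(registry, edges, label=m))
    return TemporalNetwork(registry, snaps)


class TestNodeOverlap:
    def test_identical_rows_give_one(self):
        net = snapshots_from_out_rows({"a": "bc"}, {"a": "bc"})
        assert node_overlap(*net.snapshots, 0, "out") == 1.0

    def test_disjoint_rows_give_zero(self):
        net = snapshots_from_out_rows({"a": "bc"}, {"a": "de"})
        assert node_overlap(*net.snapshots, 0, "out") == 0.0

    def test_half_shared_neighbors(self):
        # rows {b,c} then {c,d}: 1 common / sqrt(2*2)
        net = snapshots_from_out_rows({"a": "bc"}, {"a": "cd"})
        assert node_overlap(*net.snapshots, 0, "out") == pytest.approx(0.5)

    def test_empty_row_set_to_zero(self):
        net = snapshots_from_out_rows({}, {"a": "b"})
        assert node_overlap(*net.snapshots, 0, "out") == 0.0

    def test_unknown_node_rejected(self):
        net = snapshots_from_out_rows({"a": "b"}, {"a": "b"})
        with pytest.raises(ValueError):
            node_overlap(*net.snapshots, 99, "out")

    def test_mismatched_registries_rejected(self):
        a = Snapshot(NodeRegistry("ab"), {(0, 1)})
        b = Snapshot(NodeRegistry("xy"), {(0, 1)})
        with pytest.raises(ValueError):
            node_overlap(a, b, 0, "out")


class TestTransitionOverlap:
    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_identical_nonempty_snapshots_give_one(self, rng, direction):
        snap = random_network(rng, n_nodes=6, n_snapshots=2, p_edge=0.4).snapshots[0]
        if not snap.edges:
            snap = Snapshot(snap.registry, {(0, 1)})
        assert transition_overlap(snap, snap, direction) == pytest.approx(1.0)

    def test_fully_disjoint_transition_is_zero(self):
        net = snapshots_from_out_rows({"a": "b"}, {"c": "d"})
        for d in DIRECTIONS:
            assert transition_overlap(*net.snapshots, d) == 0.0

    def test_hand_worked_outgoing_example(self):
        # node a keeps 1 of 2 purchasers (1/sqrt(2)); A^out goes 1 -> 2
        net = snapshots_from_out_rows({"a": "bc"}, {"a": "b", "d": "c"})
        expected = (1 / math.sqrt(2)) / 2
        assert transition_overlap(*net.snapshots, "out") == pytest.approx(expected)

    def test_both_empty_snapshots_give_zero(self):
        registry = NodeRegistry("ab")
        empty = Snapshot(registry, set())
        assert transition_overlap(empty, empty, "out") == 0.0

    def test_node_count_normalization_flag(self):
        # classic 1/N form divides by 8 registry nodes instead of max-active
        net = snapshots_from_out_rows({"a": "bc"}, {"a": "b", "d": "c"})
        alt = transition_overlap(*net.snapshots, "out", normalization="nodes")
        assert alt == pytest.approx((1 / math.sqrt(2)) / 8)


class TestNodeAverageOverlap:
    def test_persistent_row_averages_to_one(self):
        net = snapshots_from_out_rows(*[{"a": "bc"}] * 4)
        assert node_average_overlap(net, 0, "out") == 1.0

    def test_inactive_node_averages_to_zero(self):
        net = snapshots_from_out_rows({"a": "b"}, {"a": "c"}, {"a": "b"})
        assert node_average_overlap(net, 3, "out") == 0.0

    def test_hand_worked_three_snapshot_average(self):
        # rows {b,c} -> {c,d} -> {d}: (0.5 + 1/sqrt(2)) / 2
        net = snapshots_from_out_rows({"a": "bc"}, {"a": "cd"}, {"a": "d"})
        expected = (0.5 + 1 / math.sqrt(2)) / 2
        assert node_average_overlap(net, 0, "out") == pytest.approx(expected)

    def test_single_snapshot_rejected(self):
        net = snapshots_from_out_rows({"a": "b"})
        with pytest.raises(ValueError):
            node_average_overlap(net, 0, "out")


class TestTemporalCorrelation:
    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_identical_snapshots_give_coefficient_one(self, direction):
        net = snapshots_from_out_rows(*[{"a": "bc", "d": "a"}] * 5)
        assert temporal_correlation(net, direction).network == pytest.approx(1.0)

    def test_pairwise_disjoint_snapshots_give_zero(self):
        net = snapshots_from_out_rows({"a": "b"}, {"c": "d"}, {"e": "f"})
        for d in DIRECTIONS:
            assert temporal_correlation(net, d).network == 0.0

    def test_network_value_is_mean_of_transitions(self, rng):
        for _ in range(10):
            net = random_network(rng)
            for d in DIRECTIONS:
                r = temporal_correlation(net, d)
                assert r.network == pytest.approx(r.per_transition.mean())

    def test_per_node_series_covers_registry(self, toy_network):
        r = temporal_correlation(toy_network, "out")
        assert list(r.per_node.index) == list(toy_network.registry.labels)

    def test_insufficient_snapshots_rejected(self):
        net = snapshots_from_out_rows({"a": "b"})
        with pytest.raises(ValueError):
            temporal_correlation(net, "out")


class TestOracleEquivalence:
    """Set-based implementation vs literal dense-matrix transcription."""

    def test_matches_naive_loops_on_random_networks(self, rng):
        for _ in range(40):
            net = random_network(rng, n_nodes=int(rng.integers(2, 9)),
                                 n_snapshots=int(rng.integers(2, 6)))
            for d in DIRECTIONS:
                r = temporal_correlation(net, d)
                c, per_t, per_n = naive_temporal_correlation(net, d)
                assert abs(r.network - c) < 1e-12
                np.testing.assert_allclose(r.per_transition, per_t, atol=1e-12)
                np.testing.assert_allclose(
                    r.per_node.to_numpy(), per_n, atol=1e-12
                )

    def test_matches_naive_loops_exhaustively_at_two_nodes(self):
        # all 4^3 = 64 three-snapshot networks on two nodes
        registry = NodeRegistry("ab")
        edge_sets = [set(), {(0, 1)}, {(1, 0)}, {(0, 1), (1, 0)}]
        for e1 in edge_sets:
            for e2 in edge_sets:
                for e3 in edge_sets:
                    net = TemporalNetwork(
                        registry,
                        [Snapshot(registry, e, label=m)
                         for m, e in enumerate((e1, e2, e3))],
                    )
                    for d in DIRECTIONS:
                        r = temporal_correlation(net, d)
                        c, per_t, _ = naive_temporal_correlation(net, d)
                        assert abs(r.network - c) < 1e-12
                        np.testing.assert_allclose(
                            r.per_transition, per_t, atol=1e-12
                        )


class TestStructuralInvariants:
    def test_transpose_duality_in_equals_out_of_reversed(self, rng):
        for _ in range(25):
            net = random_network(rng)
            rev = reverse(net)
            fwd = temporal_correlation(net, Direction.IN)
            bwd = temporal_correlation(rev, Direction.OUT)
            assert fwd.network == bwd.network
            assert (fwd.per_transition == bwd.per_transition).all()
            assert fwd.per_node.equals(bwd.per_node)

    def test_symmetric_networks_collapse_all_directions(self, rng):
        for _ in range(10):
            net = random_network(rng, n_nodes=8)
            sym = TemporalNetwork(
                net.registry,
                [
                    Snapshot(s.registry, s.edges | {(j, i) for i, j in s.edges})
                    for s in net.snapshots
                ],
            )
            results = [temporal_correlation(sym, d) for d in DIRECTIONS]
            for r in results[1:]:
                np.testing.assert_allclose(
                    r.per_transition, results[0].per_transition, atol=1e-12
                )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_all_quantities_in_unit_interval(self, seed):
        net = random_network(np.random.default_rng(seed))
        for d in DIRECTIONS:
            r = temporal_correlation(net, d)
            assert 0.0 <= r.network <= 1.0
            assert (r.per_transition >= 0).all()
            assert (r.per_transition <= 1).all()
            assert (r.per_node >= 0).all()
            assert (r.per_node <= 1).all()


class TestConvergenceSeries:
    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_direct_recomputation(self, toy_network, direction):
        series = convergence_series(toy_network, 12, direction)
        m = toy_network.n_snapshots
        for k, value in enumerate(series):
            extended = TemporalNetwork(
                toy_network.registry,
                list(toy_network.snapshots) + [toy_network.snapshots[-1]] * k,
            )
            direct = temporal_correlation(extended, direction).network
            assert value == pytest.approx(direct, abs=1e-12)
        assert len(series) == 12 - m + 1

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_bounded_by_one_and_non_decreasing(self, toy_network, direction):
        series = convergence_series(toy_network, 100, direction)
        assert (series <= 1.0 + 1e-12).all()
        assert (np.diff(series) >= -1e-12).all()

    def test_final_value_close_to_one(self, toy_network):
        m = toy_network.n_snapshots
        for d in DIRECTIONS:
            series = convergence_series(toy_network, 100, d)
            assert 1.0 - series[-1] < (m - 1) / 99

    def test_empty_final_snapshot_rejected(self):
        registry = NodeRegistry("ab")
        net = TemporalNetwork(
            registry, [Snapshot(registry, {(0, 1)}), Snapshot(registry, set())]
        )
        with pytest.raises(ValueError):
            convergence_series(net, 10, "out")

    def test_target_shorter_than_network_rejected(self, toy_network):
        with pytest.raises(ValueError):
            convergence_series(toy_network, 2, "out")


class TestWindowSweep:
    def test_identical_daily_records_give_one_everywhere(self):
        records = [MovementRecord(d, "a", "b") for d in range(1, 31)]
        res = window_sweep(records, [1, 2, 3, 5], 30, "out")
        assert (res.table["coefficient"] == 1.0).all()

    def test_single_burst_has_no_persistence(self):
        records = [MovementRecord(1, "a", "b"), MovementRecord(1, "c", "d")]
        res = window_sweep(records, [1, 2], 10, "out")
        assert (res.table["coefficient"] == 0.0).all()

    def test_periodic_records_peak_at_the_period(self):
        # same edge fires on days 1, 11, 21, ... (period 10), plus one-off noise
        records = [MovementRecord(d, "a", "b") for d in range(1, 200, 10)]
        records += [MovementRecord(d, f"x{d}", f"y{d}") for d in range(5, 200, 17)]
        res = window_sweep(records, range(2, 21, 2), 200, "out")
        assert res.best_length == 10

    def test_too_few_windows_reported_undefined(self):
        records = [MovementRecord(d, "a", "b") for d in range(1, 11)]
        res = window_sweep(records, [3, 6, 10], 10, "out")
        table = res.table.set_index("window_length")
        assert table.loc[10, "n_snapshots"] == 1
        assert math.isnan(table.loc[10, "coefficient"])
        assert not math.isnan(table.loc[3, "coefficient"])
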